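# Methods

## Overview

`hyenaselect` turns whole-genome DNA sequences into fixed-length per-sample
feature vectors with a small decoder-only language model built from Hyena
operators, and evaluates those vectors in a genomic-selection harness that
predicts quantitative and qualitative traits under 10-fold
cross-validation.  Every stage is deterministic under a fixed seed, and a
synthetic-data module generates genomes, SNP panels and additive traits
with known architecture so the whole pipeline is testable without external
data.

## Sequence representation and windowing

Nucleotides are tokenised one base per token with the fixed vocabulary
A=0, T=1, C=2, G=3, PAD=4, SEP=5, UNK=6.  Tokenisation is position-wise
(no k-mer merging), preserving single-nucleotide resolution; lowercase
(soft-masked) bases are uppercased rather than mapped to UNK, and any
other letter (N, IUPAC ambiguity codes) becomes UNK.  SEP is retained in
the vocabulary but never emitted inside windows.  Coordinates are 0-based
half-open internally; VCF positions are converted on ingest.

Two input modes:

* **All-sequence mode** tiles each chromosome into consecutive
  non-overlapping fragments of `L_in` tokens; the final short fragment is
  right-padded with PAD, so a chromosome of length `n` yields exactly
  `ceil(n / L_in)` windows and the unpadded window contents concatenate
  back to the chromosome.
* **SNP-sequence mode** extracts one `L_in` window per biallelic variant
  site, with `L_in/2` flanking bases on either side so the variant base
  sits at offset `L_in/2`.  Windows clipped by a chromosome end are padded
  on the clipped side rather than shifted, which keeps the variant offset
  fixed (downstream pooling masks the padding).  Overlapping windows are
  kept — one window per site.  Whatever base the supplied per-sample
  sequence carries at the site (reference or alternate) is what the model
  sees; no allele substitution happens at windowing time.

No reverse-complement augmentation is applied; sequences are used on the
given strand.

## The language model

The model is a pre-norm residual stack of `n_layer` blocks over a learned
token embedding, with a final layer norm and a linear head onto the
7-token vocabulary.  Each block applies a Hyena operator followed by a
position-wise feed-forward layer (GELU, expansion factor 2).

The Hyena operator projects its input u into three streams — two gates
x1, x2 and a value v — each via a dense layer followed by a causal
depthwise short convolution (width 3), and combines them with a long
causal convolution:

    y = x2 ⊙ ( h ∗ (x1 ⊙ v) )

where `∗` is causal convolution, i.e. multiplication by the
lower-triangular Toeplitz matrix T_h of the filter.  The filter h is not a
free parameter: each channel's impulse response is generated by a small
MLP (one hidden layer with sine activation) from deterministic positional
features — the normalised absolute index t/L_in plus sin/cos pairs at
geometrically spaced frequencies — and is optionally modulated by a
learnable per-channel exponential decay `exp(−softplus(α)·t/L_in)`
(`use_decay=True` by default, a standard stabiliser for long implicit
filters; it can be switched off for ablation).  Because the filter is a
function of position rather than a lookup table, the parameter count is
independent of `L_in`, and evaluating the convolution with zero-padded
real FFTs of length ≥ 2L−1 costs O(L log L) instead of the O(L²) Toeplitz
product.  Positional features are normalised by the fixed configured
`L_in` (not the current window length) so that filters extend consistently
when shorter windows are processed.

Every component is causal — the embedding, layer norms, dense layers and
feed-forward are position-wise; both convolutions are causal — so logits
at position t depend only on tokens at positions ≤ t.  This is asserted
directly in the test suite by suffix-perturbation probes.

**Training.** The objective is next-nucleotide cross-entropy; positions
whose target is a special token (PAD/UNK/SEP) are excluded from the loss.
Optimisation is single-device minibatch Adam at the published fine-tuning
settings (batch size 16, learning rate 6e-4, up to 6 epochs, 2 layers)
with global-norm gradient clipping at 1.0.  The model trains from scratch:
loading published pretrained genome checkpoints is out of scope, and the
mechanics of the method are unchanged by that choice.  Pre-layer
normalisation is used for depth stability.  The stack runs on a small
in-package reverse-mode autodiff engine over NumPy float64 arrays; every
custom adjoint (FFT convolution, depthwise convolution, layer norm, masked
cross-entropy) is verified against central finite differences in the test
suite, and training is bit-reproducible under a fixed seed on one device.

**Embedding.** A window's embedding is the mean of final-layer hidden
states over unpadded positions (pad-mask-weighted pooling).  Mean pooling
was chosen over max or last-token pooling as the least position-biased
option for fragments that tile a whole chromosome; the choice is isolated
behind one function and easy to ablate.

## Feature construction

Window embeddings are averaged into one vector per (sample, chromosome) —
window-count invariant and consistent with the averaging fusion
philosophy.  When the target dimension `D_vec` is below the model width, a
principal-component projection reduces each chromosome vector; inside
cross-validation this reducer is fitted on the training fold only.
Reduction happens per chromosome, before fusion.  Two fusion modes build
the per-sample vector:

* **AVERAGE** — element-wise mean across chromosomes; length `D_vec`,
  invariant to chromosome order.
* **CONCAT** — concatenation in a recorded chromosome order; length
  `n_chrom · D_vec`, with each chromosome recoverable as a contiguous
  block (20 chromosomes at `D_vec` 512 give 10,240 features).

The canonical chromosome order is the genome-file order (lexicographic
when refusing a standalone table), recorded in the output.

## Trait harness

Traits are evaluated by 10-fold cross-validation: samples are randomly
partitioned into folds whose sizes differ by at most one, each sample is
tested exactly once, and reported metrics are the arithmetic mean over
folds.  Classification folds are stratified by label so that small
categories appear in every fold — a deliberate refinement of plain random
folds, without which rare classes can vanish from training splits at desk
scale.

Quantitative targets are min–max normalised to [0, 1]; the transform is
fitted on the training fold only and applied without clipping, so
test-fold values outside the training range map outside [0, 1].  MSE and
MAE are reported on the normalised scale.  PCC is reported on the original
trait scale by inverse-transforming predictions; since min–max scaling is
affine and Pearson correlation is affine-invariant, this equals the
correlation obtained by training on raw values for any predictor whose fit
commutes with affine target scaling, and avoids a second fit per fold.
Qualitative traits report accuracy, generalised to multi-class as the
fraction of correctly classified samples (the binary
(TP+TN)/(TP+TN+FP+FN) form is also provided).  A degenerate constant
training target is handled with an identity transform (MSE 0 for a
constant predictor); correlation is undefined there and reported as NaN.

Qualitative traits are filtered before evaluation: records with missing
values are dropped, and every category with fewer than `min_count`
(default 50) samples is removed and logged.  The default cleanly separates
retained (≥235) from removed (≤37) categories in the reference category
tables this harness mirrors; the threshold is configuration, not a fitted
quantity.

Predictors are pluggable behind a registry: gradient-boosted trees
(LightGBM), random forest, extra trees, k-nearest-neighbour, ridge /
logistic regression, Bayesian ridge, a multilayer perceptron
(scikit-learn), and a small 1-D convolutional network implemented on the
package's own autodiff engine (causal convolution bank over the feature
vector, ReLU, flatten, dense head).  All predictors are seeded; those with
inherent nondeterminism are configured for reproducibility (LightGBM runs
single-threaded deterministic).

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:

* **Reference genome** — `n_chrom` chromosomes drawn i.i.d. from a stated
  base composition or from an order-1 Markov chain with a given transition
  matrix; an optional motif can be planted at a Poisson rate.
* **Population** — `n_sites` biallelic SNPs placed uniformly without
  replacement, allele frequencies drawn from `maf_range`; each haploid
  sample's sequence is the reference with its drawn alleles substituted.
  The 0/1 genotype matrix is returned as ground truth and emitted as VCF.
* **Traits** — additive genetic values g = Σ effects·dosage over `n_qtl`
  causal sites with Gaussian effects; the quantitative trait is g plus
  Gaussian noise scaled so Var(g)/Var(trait) equals the target
  heritability h²; a qualitative trait bins g at quantiles into
  `n_classes` labels.

Defaults define the desk-scale benchmark conditions used throughout the
tests and the acceptance script: 300 samples, 2 chromosomes of 10 kb, 80
SNPs of which 20 are causal, h² = 0.8.  These are the study conditions,
not tuning knobs.  Samples are haploid (one sequence per chromosome per
sample) and the architecture is purely additive; linkage disequilibrium,
recombination maps, selection and epistasis are not modelled.  Passing
tests on this generator therefore demonstrate that the pipeline recovers
additive signal carried by substituted bases in otherwise identical
genomes — they do not by themselves establish performance on real
populations with LD structure, diploidy or non-additive architecture.

## Problem sizes and numerical choices

The language-model stages run at deliberately compact sizes chosen as the
package's own desk-scale defaults: learnability checks use L_in 256,
d_model 64, 2 layers; the end-to-end benchmark uses L_in 512, d_model 64
with 2 training epochs over the reference windows.  The model width,
depth, batch size and learning-rate defaults mirror the published
fine-tuning configuration.  Key numerical choices:

* float64 throughout the model; FFT convolution matches the direct
  Toeplitz product to ~1e-15 relative error (asserted at 1e-8).
* Short-conv kernels initialise near identity (lag-0 tap 1) and the filter
  MLP's output layer starts small, so blocks begin near the residual
  identity and deepen gradually.
* The filter-MLP hidden layer uses a sine activation, the common choice
  for implicit coordinate networks.
* PCA uses the deterministic full SVD solver; fold partitions, effect
  draws and initialisations all flow from explicit integer seeds.
* All-PAD windows are rejected at pooling (nothing to average); windows
  shorter than `L_in` are processed at their natural length, which yields
  the same embedding as a PAD-extended copy (causality plus masked
  pooling — verified numerically).

## Known limitations

* The permutation-null benchmark certifies signal recovery, not absolute
  predictive accuracy; published-scale accuracies require population-scale
  data and training budgets outside this package's scope.
* SNP-mode consumers must supply per-sample sequences; the windowing layer
  does not substitute alleles itself.
* Qualitative simulation produces balanced quantile classes, which is the
  easy case for stratified CV; severely imbalanced real categories
  exercise only the filtering path.
* The 1-D CNN predictor is a deliberately small reference architecture,
  not a tuned deep-learning baseline.
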