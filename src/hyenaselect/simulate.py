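"""Synthetic genomes, variant panels and additive QTL traits.

The generator emulates the statistical structure the pipeline assumes: a
reference genome per chromosome (i.i.d. or first-order Markov base
composition), a panel of biallelic SNPs at stated allele frequencies,
haploid per-sample sequences obtained by substituting each sample's
alleles into the reference, and traits built from additive effects at a
known subset of causal sites with Gaussian noise scaled to a target
narrow-sense heritability.  Qualitative traits are derived by thresholding
the genetic value at quantiles.  Everything is deterministic under a fixed
seed, and emitted FASTA/VCF/trait files round-trip through genome_io and
the trait harness.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import GenomeSequence, VariantSite, write_fasta
from .harness import TraitRecord, TraitType, write_trait_table

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_reference",
    "simulate_population",
    "simulate_traits",
    "write_dataset",
]

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults describe the desk-scale benchmark population: 300 haploid
    samples, 2 chromosomes of 10 kb, 80 biallelic SNPs of which 20 are
    causal, additive effects, heritability 0.8.
    """

    n_samples: int = 300
    n_chrom: int = 2
    chrom_len: int = 10_000
    n_sites: int = 80
    n_qtl: int = 20
    base_composition: tuple = (0.25, 0.25, 0.25, 0.25)
    markov_order: int = 0
    transition_matrix: tuple | None = None  # 4x4 row-stochastic, order 1
    maf_range: tuple = (0.2, 0.5)
    effect_size_sd: float = 1.0
    h2: float = 0.8
    n_classes: int = 2
    motif: str | None = None
    motif_rate: float = 0.0  # expected insertions per kilobase
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=np.float64)
        if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0) or (comp < 0).any():
            raise ValueError("base_composition must be 4 non-negative probabilities summing to 1")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("heritability h2 must lie in [0, 1]")
        if self.markov_order not in (0, 1):
            raise ValueError("markov_order must be 0 or 1")
        if self.markov_order == 1:
            tm = np.asarray(self.transition_matrix, dtype=np.float64)
            if tm.shape != (4, 4) or not np.allclose(tm.sum(axis=1), 1.0):
                raise ValueError("order-1 simulation needs a 4x4 row-stochastic transition_matrix")
        if self.n_qtl > self.n_sites:
            raise ValueError("n_qtl cannot exceed the number of polymorphic sites")


@dataclass
class SimTruth:
    """Ground truth of the simulated architecture, for test assertions."""

    qtl_site_indices: list[int]
    qtl_effects: list[float]
    genetic_values: dict[str, float]
    noise_var: float
    h2: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _chrom_name(i: int) -> str:
    return f"chr{i + 1:02d}"


def _sample_name(i: int) -> str:
    return f"s{i:04d}"


def simulate_reference(config: SimConfig) -> list[GenomeSequence]:
    """Draw the reference chromosomes from the configured base process."""
    rng = np.random.default_rng(config.seed)
    comp = np.asarray(config.base_composition, dtype=np.float64)
    genomes = []
    for c in range(config.n_chrom):
        if config.markov_order == 0:
            idx = rng.choice(4, size=config.chrom_len, p=comp)
        else:
            tm = np.asarray(config.transition_matrix, dtype=np.float64)
            idx = np.empty(config.chrom_len, dtype=np.int64)
            idx[0] = rng.choice(4, p=comp)
            # cumulative-probability inversion keeps the draw vectorisable-ish
            u = rng.random(config.chrom_len)
            cum = tm.cumsum(axis=1)
            for t in range(1, config.chrom_len):
                idx[t] = np.searchsorted(cum[idx[t - 1]], u[t])
        seq = "".join(BASES[idx])
        if config.motif and config.motif_rate > 0:
            seq = _plant_motif(seq, config.motif, config.motif_rate, rng)
        genomes.append(
            GenomeSequence(sample_id="reference", chrom_id=_chrom_name(c), sequence=seq)
        )
    return genomes


def _plant_motif(seq: str, motif: str, rate_per_kb: float, rng) -> str:
    n_insert = rng.poisson(rate_per_kb * len(seq) / 1000)
    chars = list(seq)
    m = len(motif)
    for _ in range(n_insert):
        start = int(rng.integers(0, len(chars) - m))
        chars[start : start + m] = list(motif.upper())
    return "".join(chars)


def simulate_population(
    reference: Sequence[GenomeSequence], config: SimConfig
) -> tuple[dict[str, list[GenomeSequence]], list[VariantSite], np.ndarray]:
    """Place SNPs and build per-sample genomes by allele substitution.

    Returns (per-sample genomes keyed by sample_id, variant sites sorted by
    (chromosome, position), haploid 0/1 genotype matrix [n_samples, n_sites]).
    """
    rng = np.random.default_rng(config.seed + 1)
    sites: list[VariantSite] = []
    per_chrom = np.array_split(np.arange(config.n_sites), len(reference))
    for genome, chunk in zip(reference, per_chrom):
        positions = np.sort(
            rng.choice(genome.length, size=len(chunk), replace=False)
        )
        for pos in positions:
            ref_base = genome.sequence[pos]
            if ref_base not in "ACGT":  # motif or ambiguity landed here
                ref_base = "A"
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            sites.append(
                VariantSite(
                    chrom_id=genome.chrom_id,
                    pos=int(pos),
                    ref_allele=ref_base,
                    alt_allele=alt,
                )
            )
    freqs = rng.uniform(*config.maf_range, size=len(sites))
    genotypes = (rng.random((config.n_samples, len(sites))) < freqs).astype(np.int8)

    samples: dict[str, list[GenomeSequence]] = {}
    site_by_chrom: dict[str, list[tuple[int, VariantSite]]] = {}
    for j, s in enumerate(sites):
        site_by_chrom.setdefault(s.chrom_id, []).append((j, s))
    for i in range(config.n_samples):
        sid = _sample_name(i)
        chroms = []
        for genome in reference:
            chars = list(genome.sequence)
            for j, s in enumerate_sites(site_by_chrom, genome.chrom_id):
                if genotypes[i, j]:
                    chars[s.pos] = s.alt_allele
                else:
                    chars[s.pos] = s.ref_allele
            chroms.append(
                GenomeSequence(sample_id=sid, chrom_id=genome.chrom_id,
                               sequence="".join(chars))
            )
        samples[sid] = chroms
    return samples, sites, genotypes


def enumerate_sites(site_by_chrom, chrom_id):
    return site_by_chrom.get(chrom_id, [])


def simulate_traits(
    genotypes: np.ndarray, config: SimConfig
) -> tuple[list[TraitRecord], SimTruth]:
    """Additive traits: g = sum of effects * dosage; trait = g + e at target h2.

    Emits one quantitative trait ("qt") and one qualitative trait ("ql",
    ``n_classes`` quantile bins of the genetic value) per sample.
    """
    rng = np.random.default_rng(config.seed + 2)
    n, m = genotypes.shape
    qtl_idx = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    effects = rng.normal(0, config.effect_size_sd, size=config.n_qtl)
    g = genotypes[:, qtl_idx].astype(np.float64) @ effects
    var_g = float(np.var(g))
    if config.h2 == 1.0:
        if var_g == 0:
            raise ValueError("h2=1 with zero genetic variance is degenerate")
        noise_var = 0.0
        e = np.zeros(n)
    elif config.h2 == 0.0:
        noise_var = 1.0
        e = rng.normal(0, 1.0, size=n)
        g = np.zeros(n)
    else:
        noise_var = var_g * (1 - config.h2) / config.h2
        e = rng.normal(0, np.sqrt(noise_var), size=n)
    trait = g + e

    # qualitative classes from quantiles of the genetic value
    qs = np.quantile(g, np.linspace(0, 1, config.n_classes + 1)[1:-1])
    labels = np.searchsorted(qs, g, side="right")

    records: list[TraitRecord] = []
    for i in range(n):
        sid = _sample_name(i)
        records.append(TraitRecord(sid, "qt", float(trait[i]), TraitType.QUANTITATIVE))
        records.append(TraitRecord(sid, "ql", f"C{labels[i]}", TraitType.QUALITATIVE))
    truth = SimTruth(
        qtl_site_indices=qtl_idx.tolist(),
        qtl_effects=effects.tolist(),
        genetic_values={_sample_name(i): float(g[i]) for i in range(n)},
        noise_var=noise_var,
        h2=config.h2,
    )
    return records, truth


# ---------------------------------------------------------------------------
# on-disk dataset


def write_vcf(
    sites: Sequence[VariantSite],
    path,
    contig_lengths: dict[str, int],
    genotypes: np.ndarray | None = None,
    sample_ids: Sequence[str] | None = None,
) -> None:
    """Write sites (and optional haploid genotype columns) as VCF v4.2."""
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if genotypes is not None:
        cols += ["FORMAT"] + list(sample_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">\n')
        fh.write("\t".join(cols) + "\n")
        for j, s in enumerate(sites):
            row = [s.chrom_id, str(s.pos + 1), ".", s.ref_allele, s.alt_allele,
                   ".", "PASS", "."]
            if genotypes is not None:
                row += ["GT"] + [str(int(genotypes[i, j])) for i in range(genotypes.shape[0])]
            fh.write("\t".join(row) + "\n")


def write_dataset(config: SimConfig, outdir) -> dict:
    """Generate and persist a full dataset; returns a manifest dict.

    Layout: ``reference.fasta``, ``genomes/<sample>.fasta``, ``sites.vcf``,
    ``traits.tsv``, ``truth.json``.
    """
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    reference = simulate_reference(config)
    samples, sites, genotypes = simulate_population(reference, config)
    records, truth = simulate_traits(genotypes, config)

    write_fasta(reference, outdir / "reference.fasta")
    for sid, chroms in samples.items():
        write_fasta(chroms, outdir / "genomes" / f"{sid}.fasta")
    write_vcf(
        sites,
        outdir / "sites.vcf",
        contig_lengths={g.chrom_id: g.length for g in reference},
        genotypes=genotypes,
        sample_ids=list(samples),
    )
    write_trait_table(records, outdir / "traits.tsv")
    truth.to_json(outdir / "truth.json")
    manifest = {
        "n_samples": config.n_samples,
        "n_chrom": config.n_chrom,
        "chrom_len": config.chrom_len,
        "n_sites": len(sites),
        "n_qtl": config.n_qtl,
        "h2": config.h2,
        "seed": config.seed,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
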