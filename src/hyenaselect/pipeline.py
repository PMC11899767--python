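"""End-to-end orchestration: genomes -> windows -> LM -> features -> CV.

Thin glue over the library modules, shared by the command-line interface
and by reproduction scripts.  Embedding runs batched over all windows of
all samples, then aggregates window vectors by (sample, chromosome),
optionally reduces to ``D_vec`` principal components, and fuses
chromosomes by averaging or concatenation.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .fusion import (
    ChromosomeVector,
    DimReducer,
    FusionMode,
    chromosome_vector,
    feature_table,
    fuse_average,
    fuse_concat,
)
from .genome_io import GenomeSequence, VariantSite
from .harness import CVReport, TraitRecord, tenfold_cv
from .hyena_lm import HyenaConfig, HyenaModel, embed_windows, train_lm
from .windowing import Mode, window_stream

logger = logging.getLogger(__name__)

__all__ = [
    "train_on_genomes",
    "embed_samples",
    "predict_traits",
    "permutation_null_pcc",
]


def train_on_genomes(
    genomes: Sequence[GenomeSequence],
    config: HyenaConfig,
    mode: Mode = Mode.ALL_SEQUENCE,
    sites: Sequence[VariantSite] | None = None,
    val_fraction: float = 0.0,
    model: HyenaModel | None = None,
) -> HyenaModel:
    """Window the given genomes and train the LM on next-nucleotide loss."""
    windows = list(window_stream(genomes, config.l_in, mode=mode, sites=sites))
    if not windows:
        raise ValueError("no training windows could be derived from the input genomes")
    val = None
    if val_fraction > 0:
        rng = np.random.default_rng(config.seed + 7)
        n_val = max(1, int(len(windows) * val_fraction))
        idx = rng.permutation(len(windows))
        val = [windows[i] for i in idx[:n_val]]
        windows = [windows[i] for i in idx[n_val:]]
    logger.info("training on %d windows (L_in=%d)", len(windows), config.l_in)
    return train_lm(windows, config, val_corpus=val, model=model)


def embed_samples(
    model: HyenaModel,
    samples: dict[str, Sequence[GenomeSequence]],
    mode: Mode = Mode.ALL_SEQUENCE,
    sites: Sequence[VariantSite] | None = None,
    fusion: FusionMode = FusionMode.AVERAGE,
    d_vec: int | None = None,
    batch_size: int = 32,
) -> tuple[pd.DataFrame, DimReducer | None]:
    """Per-sample fused feature table from a trained model.

    Returns (feature DataFrame indexed by sample_id, fitted reducer or
    None).  When ``d_vec`` is below the model width, a principal-component
    reducer is fitted on all (sample, chromosome) vectors produced here;
    for leakage-free evaluation prefer the harness's per-fold reduction on
    full-width features.
    """
    mode = Mode(mode)
    fusion = FusionMode(fusion)
    all_windows = []
    groups: list[tuple[str, str, int]] = []  # (sample, chrom, n_windows)
    chrom_order: list[str] | None = None
    for sid, genomes in samples.items():
        order_here = [g.chrom_id for g in genomes]
        if chrom_order is None:
            chrom_order = order_here
        elif chrom_order != order_here:
            raise ValueError(
                f"sample {sid} has chromosome order {order_here}, "
                f"expected {chrom_order}"
            )
        for genome in genomes:
            ws = list(window_stream([genome], model.config.l_in, mode=mode, sites=sites))
            if not ws:
                raise ValueError(f"no windows for {sid}/{genome.chrom_id}")
            groups.append((sid, genome.chrom_id, len(ws)))
            all_windows.extend(ws)

    vecs = embed_windows(model, all_windows, batch_size=batch_size)
    chrom_vecs: list[ChromosomeVector] = []
    offset = 0
    for sid, chrom, n in groups:
        chrom_vecs.append(
            ChromosomeVector(sid, chrom, chromosome_vector(vecs[offset : offset + n]))
        )
        offset += n

    reducer = None
    if d_vec is not None and d_vec != model.config.d_model:
        mat = np.stack([cv.values for cv in chrom_vecs])
        reducer = DimReducer(d_vec).fit(mat)
        reduced = reducer.transform(mat)
        chrom_vecs = [
            ChromosomeVector(cv.sample_id, cv.chrom_id, row)
            for cv, row in zip(chrom_vecs, reduced)
        ]

    by_sample: dict[str, list[ChromosomeVector]] = {}
    for cv in chrom_vecs:
        by_sample.setdefault(cv.sample_id, []).append(cv)
    fused = []
    for sid in samples:
        if fusion is FusionMode.AVERAGE:
            fused.append(fuse_average(by_sample[sid]))
        else:
            fused.append(fuse_concat(by_sample[sid], chrom_order))
    return feature_table(fused), reducer


def predict_traits(
    features: pd.DataFrame,
    records: Sequence[TraitRecord],
    predictor_spec: str | dict = "lightgbm",
    seed: int = 1000,
    d_vec: int | None = None,
    min_count: int = 50,
) -> dict[str, CVReport]:
    """Run the 10-fold CV harness once per trait present in ``records``."""
    traits: dict[str, list[TraitRecord]] = {}
    for r in records:
        traits.setdefault(r.trait_name, []).append(r)
    overlap = {r.sample_id for r in records} & set(features.index)
    if not overlap:
        raise ValueError("no overlapping sample ids between features and traits")
    reports = {}
    for name, recs in sorted(traits.items()):
        recs = [r for r in recs if r.sample_id in features.index]
        reports[name] = tenfold_cv(
            features, recs, predictor_spec=predictor_spec, seed=seed,
            d_vec=d_vec, min_count=min_count,
        )
    return reports


def permutation_null_pcc(
    features: pd.DataFrame,
    records: Sequence[TraitRecord],
    predictor_spec: str | dict = "lightgbm",
    seed: int = 1000,
    n_perm: int = 20,
) -> np.ndarray:
    """Mean CV PCC under label shuffling, one value per permutation.

    Breaks the genotype-phenotype link while keeping the feature geometry
    and trait distribution; the resulting PCCs form the null against which
    the observed mean PCC is compared.
    """
    records = [r for r in records if not r.is_missing]
    rng = np.random.default_rng(seed + 100)
    values = [r.value for r in records]
    out = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(len(records))
        shuffled = [
            TraitRecord(r.sample_id, r.trait_name, values[perm[i]], r.trait_type)
            for i, r in enumerate(records)
        ]
        report = tenfold_cv(features, shuffled, predictor_spec=predictor_spec,
                            seed=seed)
        out[p] = report.mean_metrics["pcc"]
    return out
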