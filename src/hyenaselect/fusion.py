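"""Chromosome-level aggregation and per-sample feature fusion.

Window embeddings are averaged into one vector per (sample, chromosome),
optionally reduced to ``D_vec`` principal components (fitted on training
samples only), then fused across chromosomes either by element-wise
averaging (order-invariant, length ``D_vec``) or by concatenation in a
recorded chromosome order (length ``n_chrom * D_vec``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "FusionMode",
    "ChromosomeVector",
    "SampleFeatureVector",
    "chromosome_vector",
    "DimReducer",
    "reduce_dim",
    "fuse_average",
    "fuse_concat",
    "feature_table",
]


class FusionMode(str, Enum):
    AVERAGE = "average"
    CONCAT = "concat"


@dataclass
class ChromosomeVector:
    sample_id: str
    chrom_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError(f"non-finite chromosome vector for {self.sample_id}/{self.chrom_id}")


@dataclass
class SampleFeatureVector:
    sample_id: str
    mode: FusionMode
    values: np.ndarray
    chrom_order: list[str] | None = None  # CONCAT only


def chromosome_vector(window_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of a chromosome's window embeddings."""
    if len(window_vectors) == 0:
        raise ValueError("chromosome has no window vectors to aggregate")
    return np.mean(np.stack(window_vectors), axis=0)


class DimReducer:
    """Principal-component reduction to D_vec, identity when D_vec == width.

    Fitted on training-split chromosome vectors only; applying to unseen
    vectors uses the frozen components.
    """

    def __init__(self, d_vec: int):
        self.d_vec = d_vec
        self.components_: np.ndarray | None = None  # [D_vec, d_model]
        self.mean_: np.ndarray | None = None
        self._identity = False

    def fit(self, x: np.ndarray) -> "DimReducer":
        x = np.asarray(x, dtype=np.float64)
        d_in = x.shape[1]
        if self.d_vec > d_in:
            raise ValueError(f"D_vec {self.d_vec} exceeds input width {d_in}")
        if self.d_vec == d_in:
            self._identity = True
            return self
        if x.shape[0] < self.d_vec:
            raise ValueError(
                f"need at least {self.d_vec} fitting vectors, got {x.shape[0]}"
            )
        pca = PCA(n_components=self.d_vec, svd_solver="full", random_state=0)
        pca.fit(x)
        self.components_ = pca.components_
        self.mean_ = pca.mean_
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self._identity:
            return x.copy()
        if self.components_ is None:
            raise RuntimeError("DimReducer not fitted")
        return (x - self.mean_) @ self.components_.T

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        if self._identity:
            return np.asarray(z, dtype=np.float64).copy()
        return np.asarray(z) @ self.components_ + self.mean_

    def save(self, path) -> None:
        if self._identity:
            np.savez(path, identity=np.array([1]), d_vec=np.array([self.d_vec]))
        else:
            np.savez(
                path,
                identity=np.array([0]),
                d_vec=np.array([self.d_vec]),
                components=self.components_,
                mean=self.mean_,
            )

    @classmethod
    def load(cls, path) -> "DimReducer":
        data = np.load(path)
        red = cls(int(data["d_vec"][0]))
        if int(data["identity"][0]):
            red._identity = True
        else:
            red.components_ = data["components"]
            red.mean_ = data["mean"]
        return red


def reduce_dim(chrom_vectors: np.ndarray, d_vec: int) -> tuple[np.ndarray, DimReducer]:
    """Fit-and-apply reduction of an [n, d_model] matrix to [n, D_vec]."""
    reducer = DimReducer(d_vec).fit(chrom_vectors)
    return reducer.transform(chrom_vectors), reducer


def fuse_average(chrom_vectors: Sequence[ChromosomeVector]) -> SampleFeatureVector:
    """Element-wise mean across chromosomes (permutation-invariant)."""
    _check_one_sample(chrom_vectors)
    lengths = {len(cv.values) for cv in chrom_vectors}
    if len(lengths) != 1:
        raise ValueError(f"mixed chromosome-vector lengths {sorted(lengths)}")
    values = np.mean(np.stack([cv.values for cv in chrom_vectors]), axis=0)
    return SampleFeatureVector(
        sample_id=chrom_vectors[0].sample_id, mode=FusionMode.AVERAGE, values=values
    )


def fuse_concat(
    chrom_vectors: Sequence[ChromosomeVector], chrom_order: Sequence[str]
) -> SampleFeatureVector:
    """Concatenate chromosome vectors in ``chrom_order`` (order-sensitive)."""
    _check_one_sample(chrom_vectors)
    by_chrom = {}
    for cv in chrom_vectors:
        if cv.chrom_id in by_chrom:
            raise ValueError(f"duplicate chromosome {cv.chrom_id}")
        by_chrom[cv.chrom_id] = cv
    if sorted(by_chrom) != sorted(chrom_order) or len(set(chrom_order)) != len(chrom_order):
        raise ValueError(
            f"chrom_order {list(chrom_order)} does not match chromosomes {sorted(by_chrom)}"
        )
    values = np.concatenate([by_chrom[c].values for c in chrom_order])
    return SampleFeatureVector(
        sample_id=chrom_vectors[0].sample_id,
        mode=FusionMode.CONCAT,
        values=values,
        chrom_order=list(chrom_order),
    )


def _check_one_sample(chrom_vectors: Sequence[ChromosomeVector]) -> None:
    if len(chrom_vectors) == 0:
        raise ValueError("no chromosome vectors supplied")
    samples = {cv.sample_id for cv in chrom_vectors}
    if len(samples) != 1:
        raise ValueError(f"vectors from multiple samples: {sorted(samples)}")


def feature_table(features: Sequence[SampleFeatureVector]) -> pd.DataFrame:
    """Per-sample feature matrix as a DataFrame indexed by sample_id."""
    if not features:
        raise ValueError("no feature vectors")
    width = {len(f.values) for f in features}
    if len(width) != 1:
        raise ValueError("inconsistent feature widths across samples")
    mat = np.stack([f.values for f in features])
    index = [f.sample_id for f in features]
    cols = [f"f{i}" for i in range(mat.shape[1])]
    df = pd.DataFrame(mat, index=pd.Index(index, name="sample_id"), columns=cols)
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Write a feature table as TSV with round-trippable float text."""
    df.to_csv(path, sep="\t")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table back bit-identically (round-trip float parsing)."""
    return pd.read_csv(path, sep="\t", index_col="sample_id",
                       float_precision="round_trip")
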