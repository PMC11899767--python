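"""Trait-prediction evaluation harness.

Feature vectors are scored against traits with 10-fold cross-validation:
mean squared error, mean absolute error and Pearson's correlation for
quantitative traits, classification accuracy for qualitative ones.  Trait
values are min-max normalised inside each training fold (MSE/MAE are
reported on the normalised [0,1] scale, PCC on the original scale, which
for affine normalisation is the same correlation).  Qualitative traits are
filtered for missing values and under-represented categories before
evaluation, and their folds are stratified by label so small classes appear
in every fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .fusion import DimReducer

logger = logging.getLogger(__name__)

__all__ = [
    "TraitType",
    "TraitRecord",
    "ConfusionCounts",
    "CVReport",
    "mse",
    "mae",
    "pcc",
    "accuracy",
    "accuracy_from_labels",
    "MinMaxTransform",
    "normalize_traits",
    "filter_categories",
    "tenfold_cv",
    "run_predictor",
    "make_predictor",
    "PREDICTOR_REGISTRY",
    "read_trait_table",
    "write_trait_table",
]

MISSING = {"", "na", "nan", "none", ".", "missing"}


class TraitType(str, Enum):
    QUANTITATIVE = "quantitative"
    QUALITATIVE = "qualitative"


@dataclass
class TraitRecord:
    sample_id: str
    trait_name: str
    value: float | str | None
    trait_type: TraitType

    @property
    def is_missing(self) -> bool:
        if self.value is None:
            return True
        if self.trait_type is TraitType.QUANTITATIVE:
            try:
                return not np.isfinite(float(self.value))
            except (TypeError, ValueError):
                return True
        return str(self.value).strip().lower() in MISSING


# ---------------------------------------------------------------------------
# metrics


def _paired(y_obs, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_obs = np.asarray(y_obs, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_obs.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_obs.shape} vs {y_pred.shape}")
    if y_obs.size == 0:
        raise ValueError("empty metric inputs")
    return y_obs, y_pred


def mse(y_obs, y_pred) -> float:
    """Mean squared error (1/N) * sum (y_pred - y_obs)^2."""
    y_obs, y_pred = _paired(y_obs, y_pred)
    return float(np.mean((y_pred - y_obs) ** 2))


def mae(y_obs, y_pred) -> float:
    """Mean absolute error (1/N) * sum |y_pred - y_obs|."""
    y_obs, y_pred = _paired(y_obs, y_pred)
    return float(np.mean(np.abs(y_pred - y_obs)))


def pcc(y_obs, y_pred) -> float:
    """Pearson's correlation coefficient between observed and predicted."""
    y_obs, y_pred = _paired(y_obs, y_pred)
    if y_obs.size < 2:
        raise ValueError("PCC needs at least 2 samples")
    do = y_obs - y_obs.mean()
    dp = y_pred - y_pred.mean()
    denom = np.sqrt((do**2).sum() * (dp**2).sum())
    if denom == 0:
        raise ValueError("PCC undefined for a constant vector")
    return float((do * dp).sum() / denom)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    total = counts.tp + counts.tn + counts.fp + counts.fn
    if total == 0:
        raise ValueError("accuracy undefined for zero total count")
    return (counts.tp + counts.tn) / total


def accuracy_from_labels(y_obs, y_pred) -> float:
    """Multi-class generalisation: fraction of correctly classified samples."""
    y_obs, y_pred = np.asarray(y_obs), np.asarray(y_pred)
    if y_obs.shape != y_pred.shape or y_obs.size == 0:
        raise ValueError("label vectors must be non-empty and equal length")
    return float(np.mean(y_obs == y_pred))


# ---------------------------------------------------------------------------
# normalisation and category filtering


@dataclass
class MinMaxTransform:
    """Invertible affine map of [min, max] to [0, 1]; no clipping on apply."""

    lo: float
    span: float

    def apply(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.lo) / self.span

    def invert(self, x) -> np.ndarray:
        return np.asarray(x, dtype=np.float64) * self.span + self.lo


def normalize_traits(values) -> tuple[np.ndarray, MinMaxTransform]:
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("constant trait cannot be min-max normalised")
    tf = MinMaxTransform(lo=float(lo), span=float(hi - lo))
    return tf.apply(values), tf


def filter_categories(
    records: Sequence[TraitRecord], min_count: int = 50
) -> tuple[list[TraitRecord], dict[str, int]]:
    """Drop missing values and categories with fewer than ``min_count`` samples.

    Returns the retained records and a log of removed categories with their
    counts (missing-value records are logged under ``None``).
    """
    if not records:
        raise ValueError("no trait records supplied")
    present = [r for r in records if not r.is_missing]
    n_missing = len(records) - len(present)
    counts: dict[str, int] = {}
    for r in present:
        counts[str(r.value)] = counts.get(str(r.value), 0) + 1
    removed = {cat: n for cat, n in counts.items() if n < min_count}
    kept = [r for r in present if str(r.value) not in removed]
    if not kept:
        raise ValueError("all categories removed by the min_count filter")
    log = dict(removed)
    if n_missing:
        log["<missing>"] = n_missing
    for cat, n in sorted(removed.items()):
        logger.info("filter_categories: removed %s (n=%d < %d)", cat, n, min_count)
    return kept, log


# ---------------------------------------------------------------------------
# predictors


def _make_cnn(task: str, seed: int, **hyper):
    from .cnn import Conv1DNet

    return Conv1DNet(task=task, seed=seed, **hyper)


def _make_lightgbm(task: str, seed: int, **hyper):
    import lightgbm as lgb

    kwargs = dict(
        n_estimators=200,
        learning_rate=0.05,
        min_child_samples=5,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    kwargs.update(hyper)
    cls = lgb.LGBMRegressor if task == "regression" else lgb.LGBMClassifier
    return cls(**kwargs)


def _make_sklearn(name: str):
    def factory(task: str, seed: int, **hyper):
        from sklearn import ensemble, linear_model, neighbors, neural_network

        if name == "random_forest":
            cls = (
                ensemble.RandomForestRegressor
                if task == "regression"
                else ensemble.RandomForestClassifier
            )
            return cls(n_estimators=200, random_state=seed, n_jobs=1, **hyper)
        if name == "extra_trees":
            cls = (
                ensemble.ExtraTreesRegressor
                if task == "regression"
                else ensemble.ExtraTreesClassifier
            )
            return cls(n_estimators=200, random_state=seed, n_jobs=1, **hyper)
        if name == "knn":
            cls = (
                neighbors.KNeighborsRegressor
                if task == "regression"
                else neighbors.KNeighborsClassifier
            )
            return cls(**{"n_neighbors": 5, **hyper})
        if name == "ridge":
            if task == "regression":
                return linear_model.Ridge(**{"alpha": 1.0, **hyper})
            return linear_model.LogisticRegression(
                **{"C": 1.0, "max_iter": 2000, **hyper}
            )
        if name == "bayesian_ridge":
            if task != "regression":
                raise ValueError("bayesian_ridge supports regression only")
            return linear_model.BayesianRidge(**hyper)
        if name == "mlp":
            cls = (
                neural_network.MLPRegressor
                if task == "regression"
                else neural_network.MLPClassifier
            )
            return cls(
                **{
                    "hidden_layer_sizes": (64,),
                    "max_iter": 1000,
                    "random_state": seed,
                    **hyper,
                }
            )
        raise AssertionError(name)

    return factory


PREDICTOR_REGISTRY = {
    "lightgbm": _make_lightgbm,
    "gbdt": _make_lightgbm,  # alias: gradient-boosted decision trees
    "random_forest": _make_sklearn("random_forest"),
    "extra_trees": _make_sklearn("extra_trees"),
    "knn": _make_sklearn("knn"),
    "ridge": _make_sklearn("ridge"),
    "bayesian_ridge": _make_sklearn("bayesian_ridge"),
    "mlp": _make_sklearn("mlp"),
    "cnn": _make_cnn,
}


def make_predictor(spec: str | dict, task: str, seed: int):
    """Instantiate a registered predictor from a name or {name, params} dict."""
    if isinstance(spec, str):
        name, hyper = spec, {}
    else:
        name, hyper = spec["name"], dict(spec.get("params", {}))
    if name not in PREDICTOR_REGISTRY:
        raise KeyError(
            f"unknown predictor {name!r}; registered: {sorted(PREDICTOR_REGISTRY)}"
        )
    return PREDICTOR_REGISTRY[name](task=task, seed=seed, **hyper)


def run_predictor(spec, x_train, y_train, x_test, task: str = "regression",
                  seed: int = 1000) -> np.ndarray:
    """Fit a registered predictor and return predictions for the test rows."""
    import warnings

    model = make_predictor(spec, task=task, seed=seed)
    with warnings.catch_warnings():
        # lightgbm's sklearn wrapper warns about feature names even for
        # plain ndarray inputs; the pipeline is name-free by construction
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        model.fit(np.asarray(x_train), np.asarray(y_train))
        return np.asarray(model.predict(np.asarray(x_test)))


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVReport:
    trait_name: str
    predictor_name: str
    trait_type: str
    fold_metrics: list[dict] = field(default_factory=list)
    mean_metrics: dict = field(default_factory=dict)
    n_samples: int = 0
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        rows = [dict(fold=i, **m) for i, m in enumerate(self.fold_metrics)]
        rows.append(dict(fold="mean", **self.mean_metrics))
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_json(cls, path) -> "CVReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator,
                  labels: np.ndarray | None = None) -> list[np.ndarray]:
    """Random (optionally label-stratified) partition into n_folds folds.

    Plain partitions have fold sizes differing by at most one; stratified
    partitions distribute each label's samples round-robin after a shuffle.
    """
    if labels is None:
        perm = rng.permutation(n)
        return [perm[i::n_folds] for i in range(n_folds)]
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    offset = 0
    for lab in sorted(set(labels.tolist())):
        idx = rng.permutation(np.flatnonzero(labels == lab))
        for j, i in enumerate(idx):
            folds[(offset + j) % n_folds].append(int(i))
        offset += len(idx)
    return [np.array(sorted(f), dtype=np.int64) for f in folds]


def tenfold_cv(
    features: pd.DataFrame,
    records: Sequence[TraitRecord],
    predictor_spec: str | dict = "lightgbm",
    seed: int = 1000,
    n_folds: int = 10,
    d_vec: int | None = None,
    min_count: int = 50,
) -> CVReport:
    """Cross-validated evaluation of one trait on a per-sample feature table.

    ``features`` is indexed by sample_id; ``records`` all belong to one
    trait.  Each sample is tested exactly once; trait normalisation and any
    dimension reduction are fitted on the training fold only.  With a fixed
    seed the partition, and hence the report, is fully reproducible.
    """
    records = [r for r in records if not r.is_missing]
    if not records:
        raise ValueError("no non-missing trait records")
    names = {r.trait_name for r in records}
    if len(names) != 1:
        raise ValueError(f"records span multiple traits: {sorted(names)}")
    trait_type = records[0].trait_type
    if trait_type is TraitType.QUALITATIVE:
        records, _ = filter_categories(records, min_count=min_count)
    missing_ids = [r.sample_id for r in records if r.sample_id not in features.index]
    if missing_ids:
        raise ValueError(f"trait samples absent from feature table: {missing_ids[:5]}")
    records = sorted(records, key=lambda r: r.sample_id)
    n = len(records)
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} samples, got {n}")
    x = features.loc[[r.sample_id for r in records]].to_numpy(dtype=np.float64)
    rng = np.random.default_rng(seed)

    pred_name = predictor_spec if isinstance(predictor_spec, str) else predictor_spec["name"]
    report = CVReport(
        trait_name=records[0].trait_name,
        predictor_name=pred_name,
        trait_type=trait_type.value,
        n_samples=n,
        seed=seed,
    )

    if trait_type is TraitType.QUANTITATIVE:
        y = np.array([float(r.value) for r in records])
        folds = _fold_indices(n, n_folds, rng)
        task = "regression"
    else:
        y = np.array([str(r.value) for r in records])
        folds = _fold_indices(n, n_folds, rng, labels=y)
        task = "classification"

    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        x_tr, x_te = x[train_idx], x[test_idx]
        if d_vec is not None and d_vec < x.shape[1]:
            reducer = DimReducer(d_vec).fit(x_tr)
            x_tr, x_te = reducer.transform(x_tr), reducer.transform(x_te)
        if task == "regression":
            if np.ptp(y[train_idx]) == 0:  # constant training target
                tf = MinMaxTransform(lo=float(y[train_idx][0]), span=1.0)
                y_norm = tf.apply(y[train_idx])
            else:
                y_norm, tf = normalize_traits(y[train_idx])
            pred_norm = run_predictor(
                predictor_spec, x_tr, y_norm, x_te, task=task, seed=seed + k
            )
            obs_norm = tf.apply(y[test_idx])
            try:
                fold_pcc = pcc(y[test_idx], tf.invert(pred_norm))
            except ValueError:  # constant fold: correlation undefined
                fold_pcc = float("nan")
            fold = {
                "mse": mse(obs_norm, pred_norm),
                "mae": mae(obs_norm, pred_norm),
                "pcc": fold_pcc,
            }
        else:
            pred = run_predictor(
                predictor_spec, x_tr, y[train_idx], x_te, task=task, seed=seed + k
            )
            fold = {"accuracy": accuracy_from_labels(y[test_idx], pred)}
        report.fold_metrics.append(fold)

    report.mean_metrics = {
        key: float(np.mean([f[key] for f in report.fold_metrics]))
        for key in report.fold_metrics[0]
    }
    return report


# ---------------------------------------------------------------------------
# trait table I/O (TSV: sample_id, trait_name, value, type)


def read_trait_table(path) -> list[TraitRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "trait_name", "value", "type"}
    if not required.issubset(df.columns):
        raise ValueError(f"trait table must have columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        ttype = TraitType(row.type)
        value: float | str | None = row.value
        if ttype is TraitType.QUANTITATIVE:
            try:
                value = float(row.value)
            except ValueError:
                value = None
        out.append(
            TraitRecord(
                sample_id=row.sample_id,
                trait_name=row.trait_name,
                value=value,
                trait_type=ttype,
            )
        )
    return out


def write_trait_table(records: Sequence[TraitRecord], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "trait_name": r.trait_name,
            "value": "" if r.value is None else r.value,
            "type": r.trait_type.value,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
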