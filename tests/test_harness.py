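import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hyenaselect import (
    ConfusionCounts,
    TraitRecord,
    TraitType,
    accuracy,
    accuracy_from_labels,
    filter_categories,
    mae,
    mse,
    normalize_traits,
    pcc,
    run_predictor,
    tenfold_cv,
)
from hyenaselect.harness import (
    _fold_indices,
    make_predictor,
    read_trait_table,
    write_trait_table,
)
from hyenaselect.fusion import DimReducer

# printed flower-colour category sizes used as an in-repo fixture
FC_COUNTS = {"P": 3227, "W": 1631, "Dp": 30, "B": 5, "Lp": 5, "Pth": 4}


def records_from_counts(counts, trait="FC"):
    out = []
    i = 0
    for cat, n in counts.items():
        for _ in range(n):
            out.append(TraitRecord(f"s{i:05d}", trait, cat, TraitType.QUALITATIVE))
            i += 1
    return out


class TestMetrics:
    def test_perfect_prediction_identities(self, rng):
        y = rng.normal(size=50)
        assert mse(y, y) == 0.0
        assert mae(y, y) == 0.0
        assert pcc(y, 2 * y + 1) == pytest.approx(1.0, abs=1e-12)
        assert accuracy(ConfusionCounts(tp=5, tn=3, fp=0, fn=0)) == 1.0

    def test_closed_forms(self):
        assert mse([0, 1], [1, 0]) == 1.0
        assert mae([0, 0], [3, -3]) == 3.0
        assert pcc([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0, abs=1e-12)
        assert accuracy(ConfusionCounts(tp=2, tn=1, fp=1, fn=0)) == 0.75
        assert accuracy(ConfusionCounts(tp=0, tn=0, fp=3, fn=2)) == 0.0

    def test_loop_oracles_on_random_inputs(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 1000))
            a, b = rng.normal(size=n), rng.normal(size=n)
            assert mse(a, b) == pytest.approx(sum((x - y) ** 2 for x, y in zip(a, b)) / n, abs=1e-12)
            assert mae(a, b) == pytest.approx(sum(abs(x - y) for x, y in zip(a, b)) / n, abs=1e-12)
            assert pcc(a, b) == pytest.approx(stats.pearsonr(a, b).statistic, abs=1e-12)

    def test_mae_bounded_by_rmse(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 50))
            a, b = rng.normal(size=n), rng.normal(size=n)
            assert mae(a, b) <= np.sqrt(mse(a, b)) + 1e-12

    def test_pcc_guards(self):
        with pytest.raises(ValueError):
            pcc([1.0], [2.0])
        with pytest.raises(ValueError):
            pcc([1, 1, 1], [1, 2, 3])

    def test_accuracy_guards(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_multiclass_accuracy(self):
        assert accuracy_from_labels(["a", "b", "c", "a"], ["a", "b", "a", "a"]) == 0.75


class TestNormalisation:
    def test_closed_form(self):
        normed, tf = normalize_traits([0.0, 5.0, 10.0])
        np.testing.assert_allclose(normed, [0, 0.5, 1])

    def test_round_trip(self, rng):
        x = rng.normal(size=100) * 7 + 3
        normed, tf = normalize_traits(x)
        np.testing.assert_allclose(tf.invert(normed), x, atol=1e-12)

    def test_no_clipping_beyond_training_range(self):
        _, tf = normalize_traits([0.0, 10.0])
        assert tf.apply([15.0])[0] == 1.5

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError):
            normalize_traits([2.0, 2.0, 2.0])


class TestFilterCategories:
    def test_printed_flower_colour_counts(self):
        kept, log = filter_categories(records_from_counts(FC_COUNTS), min_count=50)
        assert {str(r.value) for r in kept} == {"P", "W"}
        assert len(kept) == 3227 + 1631
        assert set(log) == {"Dp", "B", "Lp", "Pth"}

    def test_all_large_categories_unchanged(self):
        recs = records_from_counts({"a": 60, "b": 55})
        kept, log = filter_categories(recs, min_count=50)
        assert len(kept) == 115 and log == {}

    def test_missing_values_dropped_and_logged(self):
        recs = records_from_counts({"a": 60}) + [
            TraitRecord("x1", "FC", None, TraitType.QUALITATIVE),
            TraitRecord("x2", "FC", "NA", TraitType.QUALITATIVE),
        ]
        kept, log = filter_categories(recs, min_count=50)
        assert len(kept) == 60 and log["<missing>"] == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            filter_categories([])

    def test_everything_removed_rejected(self):
        with pytest.raises(ValueError, match="all categories"):
            filter_categories(records_from_counts({"a": 3, "b": 2}), min_count=50)


class TestFoldPartition:
    def test_true_partition_for_all_sizes(self, rng):
        for n in range(20, 201):
            folds = _fold_indices(n, 10, np.random.default_rng(n))
            sizes = [len(f) for f in folds]
            assert max(sizes) - min(sizes) <= 1
            joined = np.sort(np.concatenate(folds))
            np.testing.assert_array_equal(joined, np.arange(n))

    def test_stratified_partition_covers_all_and_balances_labels(self, rng):
        labels = np.array(["a"] * 55 + ["b"] * 25 + ["c"] * 20)
        folds = _fold_indices(100, 10, rng, labels=labels)
        joined = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(joined, np.arange(100))
        for f in folds:
            counts = pd.Series(labels[f]).value_counts()
            assert counts.get("a", 0) in (5, 6)
            assert counts.get("c", 0) in (1, 2, 3)


def linear_dataset(rng, n=100, d=8, noise=0.0):
    x = rng.normal(size=(n, d))
    beta = rng.normal(size=d)
    y = x @ beta + noise * rng.normal(size=n)
    features = pd.DataFrame(
        x, index=pd.Index([f"s{i:03d}" for i in range(n)], name="sample_id"),
        columns=[f"f{j}" for j in range(d)],
    )
    records = [
        TraitRecord(f"s{i:03d}", "qt", float(y[i]), TraitType.QUANTITATIVE)
        for i in range(n)
    ]
    return features, records


class TestTenfoldCV:
    def test_fold_sizes_and_report_shape(self, rng):
        features, records = linear_dataset(rng, n=95)
        report = tenfold_cv(features, records, predictor_spec="ridge", seed=3)
        assert len(report.fold_metrics) == 10
        assert report.n_samples == 95
        for key in ("mse", "mae", "pcc"):
            assert key in report.mean_metrics
        recomputed = np.mean([f["mse"] for f in report.fold_metrics])
        assert report.mean_metrics["mse"] == pytest.approx(recomputed, abs=1e-15)

    def test_noise_free_linear_target_is_recovered(self, rng):
        features, records = linear_dataset(rng, n=100, noise=0.0)
        report = tenfold_cv(features, records, predictor_spec="ridge", seed=3)
        assert report.mean_metrics["pcc"] > 0.99
        assert report.mean_metrics["mse"] < 1e-3

    def test_constant_target_constant_predictor_gives_zero_mse(self, rng):
        features, records = linear_dataset(rng, n=40)
        const = [
            TraitRecord(r.sample_id, "qt", 5.0, TraitType.QUANTITATIVE) for r in records
        ]
        report = tenfold_cv(features, const, predictor_spec="knn", seed=3)
        assert report.mean_metrics["mse"] == 0.0

    def test_fixed_seed_identical_reports(self, rng):
        features, records = linear_dataset(rng, n=60, noise=0.5)
        a = tenfold_cv(features, records, predictor_spec="lightgbm", seed=11)
        b = tenfold_cv(features, records, predictor_spec="lightgbm", seed=11)
        assert a.fold_metrics == b.fold_metrics

    def test_unmatched_sample_ids_rejected(self, rng):
        features, records = linear_dataset(rng, n=40)
        records.append(TraitRecord("ghost", "qt", 1.0, TraitType.QUANTITATIVE))
        with pytest.raises(ValueError, match="ghost"):
            tenfold_cv(features, records, seed=1)

    def test_too_few_samples_rejected(self, rng):
        features, records = linear_dataset(rng, n=15)
        with pytest.raises(ValueError, match="at least"):
            tenfold_cv(features, records, seed=1)

    def test_classification_report(self, rng):
        n = 80
        x = rng.normal(size=(n, 4))
        labels = np.where(x[:, 0] > 0, "hi", "lo")
        features = pd.DataFrame(
            x, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        )
        records = [
            TraitRecord(f"s{i}", "ql", labels[i], TraitType.QUALITATIVE)
            for i in range(n)
        ]
        report = tenfold_cv(features, records, predictor_spec="ridge", seed=5,
                            min_count=5)
        assert set(report.fold_metrics[0]) == {"accuracy"}
        assert report.mean_metrics["accuracy"] > 0.8

    def test_per_fold_reduction_differs_from_leaky_reduction(self, rng):
        """Fitting PCA on all samples before CV leaks test-fold geometry;
        the harness's per-fold path must not equal that leaky pipeline."""
        n, d = 60, 20
        x = rng.normal(size=(n, d))
        x[: n // 2] += 3.0  # strong structure so PCA fit depends on the split
        y = x[:, 0] + 0.1 * rng.normal(size=n)
        idx = pd.Index([f"s{i:03d}" for i in range(n)], name="sample_id")
        features = pd.DataFrame(x, index=idx)
        records = [
            TraitRecord(f"s{i:03d}", "qt", float(y[i]), TraitType.QUANTITATIVE)
            for i in range(n)
        ]
        clean = tenfold_cv(features, records, predictor_spec="ridge", seed=2, d_vec=2)
        leaky_features = pd.DataFrame(
            DimReducer(2).fit(x).transform(x), index=idx
        )
        leaky = tenfold_cv(leaky_features, records, predictor_spec="ridge", seed=2)
        assert clean.mean_metrics["mse"] != leaky.mean_metrics["mse"]


class TestPredictors:
    def test_unknown_name_lists_registry(self):
        with pytest.raises(KeyError, match="registered"):
            make_predictor("nonsense", task="regression", seed=0)

    def test_knn_memorises_training_set(self, rng):
        x = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        preds = run_predictor(
            {"name": "knn", "params": {"n_neighbors": 1}}, x, y, x, seed=0
        )
        np.testing.assert_allclose(preds, y, atol=1e-12)

    def test_ridge_fits_collinear_target(self, rng):
        x = rng.normal(size=(50, 5))
        y = x @ np.arange(1.0, 6.0)
        preds = run_predictor(
            {"name": "ridge", "params": {"alpha": 1e-8}}, x, y, x, seed=0
        )
        assert mse(y, preds) < 1e-6

    @pytest.mark.parametrize("name", ["lightgbm", "random_forest", "extra_trees", "mlp"])
    def test_deterministic_under_seed(self, rng, name):
        x = rng.normal(size=(60, 5))
        y = x[:, 0] + rng.normal(size=60)
        a = run_predictor(name, x, y, x[:10], seed=9)
        b = run_predictor(name, x, y, x[:10], seed=9)
        np.testing.assert_array_equal(a, b)

    def test_cnn_regression_learns_strong_signal(self, rng):
        x = rng.normal(size=(80, 12))
        y = 2.0 * x[:, 3]
        spec = {"name": "cnn", "params": {"epochs": 150}}
        preds = run_predictor(spec, x, y, x, seed=0)
        assert pcc(y, preds) > 0.9

    def test_cnn_classification_labels(self, rng):
        x = rng.normal(size=(60, 10))
        y = np.where(x[:, 0] > 0, "a", "b")
        spec = {"name": "cnn", "params": {"epochs": 100}}
        preds = run_predictor(spec, x, y, x, task="classification", seed=0)
        assert set(preds) <= {"a", "b"}
        assert accuracy_from_labels(y, preds) > 0.8

    def test_bayesian_ridge_classification_rejected(self):
        with pytest.raises(ValueError):
            make_predictor("bayesian_ridge", task="classification", seed=0)


class TestTraitTable:
    def test_round_trip(self, tmp_path):
        records = [
            TraitRecord("s1", "qt", 1.5, TraitType.QUANTITATIVE),
            TraitRecord("s2", "qt", None, TraitType.QUANTITATIVE),
            TraitRecord("s1", "ql", "purple", TraitType.QUALITATIVE),
        ]
        path = tmp_path / "traits.tsv"
        write_trait_table(records, path)
        back = read_trait_table(path)
        assert back[0].value == 1.5
        assert back[1].is_missing
        assert back[2].value == "purple"
        assert back[2].trait_type is TraitType.QUALITATIVE
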