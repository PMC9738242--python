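"""Repeated-CV harness and GA feature selection behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wristbow.modeling import (
    CLASSIFIER_IDS,
    CVSettings,
    GAConfig,
    evaluate_feature_sets,
    ga_select,
    make_classifier,
    run_cv,
    summarize_results,
)


def planted_data(rng, n=40, n_noise=5, separation=6.0):
    y = np.array(["HE"] * (n // 2) + ["PD"] * (n - n // 2))
    X = rng.normal(size=(n, n_noise + 1))
    X[:, 0] = np.where(y == "PD", separation, 0.0) + rng.normal(size=n)
    return X, y


class TestRunCV:
    def test_separable_data_perfect_svm(self, rng):
        X, y = planted_data(rng, separation=20.0)
        res = run_cv(X, y, "SVM", CVSettings(n_runs=5, folds=5), seed=0)
        assert np.all(res.accuracies == 1.0)
        assert np.all(res.aucs == 1.0)

    def test_shuffled_labels_near_chance(self, rng):
        """Label-independent features give accuracy inside the 99% binomial
        band around 0.5."""
        n = 60
        X = rng.normal(size=(n, 8))
        y = np.array(["HE"] * 30 + ["PD"] * 30)
        res = run_cv(X, y, "SVM", CVSettings(n_runs=40, folds=10), seed=1)
        half_width = 2.576 * np.sqrt(0.25 / n)
        assert abs(res.mean_accuracy - 0.5) < half_width

    def test_deterministic(self, rng):
        X, y = planted_data(rng, separation=1.0)
        a = run_cv(X, y, "RF", CVSettings(n_runs=3, folds=5), seed=9)
        b = run_cv(X, y, "RF", CVSettings(n_runs=3, folds=5), seed=9)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        np.testing.assert_array_equal(a.aucs, b.aucs)

    def test_column_permutation_invariance(self, rng):
        """Distance/likelihood classifiers are invariant to feature order."""
        X, y = planted_data(rng, separation=1.5)
        perm = rng.permutation(X.shape[1])
        for cid in ("SVM", "NB", "KNN"):
            a = run_cv(X, y, cid, CVSettings(n_runs=3, folds=5), seed=2)
            b = run_cv(X[:, perm], y, cid, CVSettings(n_runs=3, folds=5), seed=2)
            np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_stratification_keeps_both_classes(self, rng):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([0] * 40 + [1] * 20)
        cv = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        for _, test in cv.split(np.zeros((60, 1)), y):
            assert len(np.unique(y[test])) == 2

    def test_errors(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="two classes"):
            run_cv(X, np.zeros(10), "SVM", CVSettings(n_runs=1, folds=2))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="folds"):
            run_cv(X, y, "SVM", CVSettings(n_runs=1, folds=11))
        with pytest.raises(ValueError, match="classifier"):
            make_classifier("XGB", 0)

    @pytest.mark.parametrize("cid", CLASSIFIER_IDS)
    def test_all_six_classifiers_run(self, rng, cid):
        X, y = planted_data(rng, separation=3.0)
        res = run_cv(X, y, cid, CVSettings(n_runs=2, folds=5), seed=0)
        assert res.accuracies.shape == (2,)
        assert np.all((0 <= res.accuracies) & (res.accuracies <= 1))


class TestEvaluateFeatureSets:
    def test_plan_shapes_and_determinism(self, rng):
        X, y = planted_data(rng, separation=2.0)
        idx = [f"S{i}" for i in range(len(y))]
        table = pd.DataFrame(X, index=idx)
        labels = pd.Series(y, index=idx)
        plan = {"a": table, "b": table}
        settings = CVSettings(n_runs=2, folds=5, compute_auc=False)
        r1 = evaluate_feature_sets(plan, labels, ["SVM"], settings, seed=3)
        r2 = evaluate_feature_sets(plan, labels, ["SVM"], settings, seed=3)
        assert len(r1) == 2
        for key in r1:
            assert r1[key].accuracies.shape == (2,)
            np.testing.assert_array_equal(r1[key].accuracies, r2[key].accuracies)
        summary = summarize_results(r1)
        assert summary.shape == (2, 1)
        assert "±" in summary.iloc[0, 0]

    def test_mismatched_subjects_rejected(self, rng):
        X, y = planted_data(rng)
        t1 = pd.DataFrame(X, index=[f"S{i}" for i in range(len(y))])
        t2 = t1.copy()
        t2.index = [f"T{i}" for i in range(len(y))]
        labels = pd.Series(y, index=t1.index)
        with pytest.raises(ValueError, match="subject ids"):
            evaluate_feature_sets({"a": t1, "b": t2}, labels, ["NB"], CVSettings(1, 2))


class TestGA:
    def make_table(self, rng, n_noise=30, n=40):
        X, y = planted_data(rng, n=n, n_noise=n_noise, separation=8.0)
        cols = ["planted"] + [f"noise{i}" for i in range(n_noise)]
        idx = [f"S{i}" for i in range(n)]
        return pd.DataFrame(X, index=idx, columns=cols), pd.Series(y, index=idx)

    def test_planted_feature_recovered_across_seeds(self, rng):
        hits = 0
        n_runs = 10
        for seed in range(n_runs):
            table, labels = self.make_table(np.random.default_rng(seed))
            mask = ga_select(
                table, labels,
                GAConfig(population_size=20, generations=6, parents_selected=10, seed=seed),
                CVSettings(n_runs=1, folds=5, compute_auc=False),
                classifier_ids=("NB",),
            )
            hits += "planted" in mask.selected
        assert hits >= n_runs - 1

    def test_trace_non_decreasing(self, rng):
        table, labels = self.make_table(rng, n_noise=10)
        mask = ga_select(
            table, labels,
            GAConfig(population_size=10, generations=5, parents_selected=6, seed=0),
            CVSettings(n_runs=1, folds=4, compute_auc=False),
            classifier_ids=("DT",),
        )
        trace = np.asarray(mask.fitness_trace)
        assert trace.size == 6
        assert np.all(np.diff(trace) >= 0)
        assert mask.fitness == trace[-1]

    def test_zero_generations_returns_best_initial(self, rng):
        table, labels = self.make_table(rng, n_noise=5)
        mask = ga_select(
            table, labels,
            GAConfig(population_size=8, generations=0, parents_selected=4, seed=1),
            CVSettings(n_runs=1, folds=4, compute_auc=False),
            classifier_ids=("NB",),
        )
        assert len(mask.fitness_trace) == 1
        assert mask.mask.any()

    def test_identical_copies_degenerate_tie(self, rng):
        n = 24
        y = pd.Series(["HE", "PD"] * (n // 2), index=[f"S{i}" for i in range(n)])
        col = rng.normal(size=n)
        table = pd.DataFrame(
            {f"c{i}": col for i in range(4)}, index=y.index
        )
        mask = ga_select(
            table, y,
            GAConfig(population_size=6, generations=2, parents_selected=4, sparsity_weight=0.0, seed=0),
            CVSettings(n_runs=1, folds=3, compute_auc=False),
            classifier_ids=("NB",),
        )
        assert mask.mask.any()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ga_select(pd.DataFrame(index=["a", "b"]), pd.Series(["x", "y"], index=["a", "b"]))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=4, parents_selected=10)
        with pytest.raises(ValueError):
            GAConfig(mutation_prob=1.2)


def test_nested_ga_cv_runs_leak_free(rng):
    """Nested GA selection evaluates without exposing held-out subjects."""
    from wristbow.modeling import nested_ga_cv

    X, y = planted_data(rng, n=30, n_noise=6, separation=8.0)
    idx = [f"S{i}" for i in range(len(y))]
    table = pd.DataFrame(X, index=idx, columns=[f"f{i}" for i in range(X.shape[1])])
    labels = pd.Series(y, index=idx)
    res = nested_ga_cv(
        table, labels, classifier_id="NB",
        ga_config=GAConfig(population_size=6, generations=1, parents_selected=4),
        ga_cv=CVSettings(n_runs=1, folds=3, compute_auc=False),
        settings=CVSettings(n_runs=2, folds=3, compute_auc=False),
        seed=4,
    )
    assert res.accuracies.shape == (2,)
    # planted signal is strong enough that leak-free accuracy is still high
    assert res.mean_accuracy > 0.8
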