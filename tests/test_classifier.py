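import numpy as np
import pytest

from petrad.classifier import (
    BalancedRandomForest,
    BRFConfig,
    ConfusionMetrics,
    balanced_bootstrap,
    evaluate,
    fit_brf,
    reconstruct_confusion_matrices,
)


class TestBalancedBootstrap:
    def test_definition(self, rng):
        labels = np.array([1] * 10 + [0] * 30)
        idx = balanced_bootstrap(labels, rng)
        assert len(idx) == 20
        counts = np.bincount(labels[idx])
        assert counts[0] == 10 and counts[1] == 10

    def test_balanced_input_reduces_to_half_bootstrap(self, rng):
        labels = np.array([0] * 15 + [1] * 15)
        idx = balanced_bootstrap(labels, rng)
        assert len(idx) == 30
        assert np.bincount(labels[idx])[0] == 15

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError):
            balanced_bootstrap(np.ones(10), rng)

    def test_inclusion_frequency_matches_closed_form(self, rng):
        # each majority item is drawn n_min times from 30 candidates per tree:
        # P(in tree) = 1 - (1 - 1/30)^10
        labels = np.array([1] * 10 + [0] * 30)
        n_trees = 1000
        included = np.zeros(40)
        for _ in range(n_trees):
            included[np.unique(balanced_bootstrap(labels, rng))] += 1
        p = 1 - (1 - 1 / 30) ** 10
        se = np.sqrt(p * (1 - p) / n_trees)
        maj_freq = included[10:] / n_trees
        assert abs(maj_freq.mean() - p) < 3 * se


class TestBalancedRandomForest:
    def test_every_tree_balanced(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.array([1] * 10 + [0] * 30)
        model = BalancedRandomForest(n_estimators=20, random_state=1).fit(X, y)
        for idx in model.bootstrap_indices_:
            counts = np.bincount(y[idx])
            assert counts[0] == counts[1] == 10

    def test_stump_separates_1d(self):
        X = np.array([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = BalancedRandomForest(n_estimators=1, max_depth=1, random_state=0).fit(X, y)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, model.predict_proba(X)[:, 1]) == 1.0

    def test_determinism(self, rng):
        X = rng.standard_normal((30, 4))
        y = (rng.random(30) < 0.4).astype(int)
        p1 = BalancedRandomForest(n_estimators=15, random_state=7).fit(X, y).predict_proba(X)
        p2 = BalancedRandomForest(n_estimators=15, random_state=7).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)


class TestFitBrf:
    def _data(self, rng, n=60, signal=2.0):
        X = rng.standard_normal((n, 3))
        logit = signal * X[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        if y.sum() < 5:
            y[:5] = 1
        return X, y

    def _config(self):
        return BRFConfig(
            max_depth=(3,), n_estimators=(25,), min_samples_split=(2,),
            min_samples_leaf=(1,), max_features=("sqrt",), bootstrap=(True,),
            criterion=("gini", "entropy"), cv_folds=3, seed=0,
        )

    def test_grid_search_deterministic(self, rng):
        X, y = self._data(rng)
        _, r1 = fit_brf(X, y, self._config())
        _, r2 = fit_brf(X, y, self._config())
        assert r1["best_params"] == r2["best_params"]
        assert r1["best_cv_auc"] == r2["best_cv_auc"]

    def test_signal_detected_vs_null(self, rng):
        X, y = self._data(rng, n=80, signal=3.0)
        _, report = fit_brf(X, y, self._config())
        assert report["best_cv_auc"] > 0.65

    def test_single_class_raises(self, rng):
        X = rng.standard_normal((20, 2))
        with pytest.raises(ValueError):
            fit_brf(X, np.zeros(20, int), self._config())


class TestEvaluate:
    def test_confusion_arithmetic(self):
        m = ConfusionMetrics(tp=9, fn=2, tn=6, fp=3)
        assert m.sensitivity == pytest.approx(9 / 11)
        assert m.specificity == pytest.approx(6 / 9)
        assert m.accuracy == pytest.approx(0.75)
        d = m.as_dict()
        assert (d["sensitivity"], d["specificity"], d["accuracy"]) == (0.82, 0.67, 0.75)

    def test_perfect_predictor(self, rng):
        X = np.linspace(0, 1, 20)[:, None]
        y = (X[:, 0] > 0.5).astype(int)
        model = BalancedRandomForest(n_estimators=5, random_state=0).fit(X, y)
        metrics, roc = evaluate(model, X, y)
        assert metrics.auc == 1.0
        assert metrics.fp == 0 and metrics.fn == 0

    def test_auc_equals_mann_whitney(self, rng):
        from scipy.stats import mannwhitneyu

        X = rng.standard_normal((50, 2))
        y = (rng.random(50) < 0.4).astype(int)
        model = BalancedRandomForest(n_estimators=10, random_state=3).fit(X, y)
        metrics, _ = evaluate(model, X, y)
        proba = model.predict_proba(X)[:, 1]
        u = mannwhitneyu(proba[y == 1], proba[y == 0]).statistic
        assert metrics.auc == pytest.approx(u / (y.sum() * (y == 0).sum()))

    def test_one_class_test_raises(self, rng):
        X = rng.standard_normal((10, 2))
        y = (rng.random(10) < 0.5).astype(int)
        model = BalancedRandomForest(n_estimators=5, random_state=0).fit(X, y)
        with pytest.raises(ValueError):
            evaluate(model, X, np.ones(10, int))

    def test_auc_invariant_to_monotone_transform(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(40)
        y = (rng.random(40) < 0.5).astype(int)
        y[0], y[1] = 0, 1
        assert roc_auc_score(y, scores) == pytest.approx(
            roc_auc_score(y, np.log(scores + 1e-9))
        )

    def test_permutation_null_centered(self, rng):
        X = rng.standard_normal((40, 2))
        y = np.array([0, 1] * 20)
        model = BalancedRandomForest(n_estimators=10, random_state=1).fit(X, y)
        proba = model.predict_proba(X)[:, 1]
        from sklearn.metrics import roc_auc_score

        aucs = []
        for _ in range(100):
            aucs.append(roc_auc_score(rng.permutation(y), proba))
        assert abs(np.mean(aucs) - 0.5) < 0.03


class TestReconstruction:
    PRINTED = {
        "clinical": (0.64, 0.56),
        "radiomics": (0.82, 0.67),
        "composite": (0.82, 0.56),
    }

    def test_unique_reconstruction_matches_reported_accuracies(self):
        rec = reconstruct_confusion_matrices(self.PRINTED, 20)
        assert round(rec["clinical"].accuracy, 2) == 0.6
        assert round(rec["radiomics"].accuracy, 2) == 0.75
        assert round(rec["composite"].accuracy, 2) == 0.7

    def test_reconstructed_counts(self):
        rec = reconstruct_confusion_matrices(self.PRINTED, 20)
        m = rec["radiomics"]
        assert (m.tp, m.fn, m.tn, m.fp) == (9, 2, 6, 3)
        # all models share the same class split: 11 positive / 9 negative
        for cm in rec.values():
            assert cm.tp + cm.fn == 11 and cm.tn + cm.fp == 9

    def test_inconsistent_rates_raise(self):
        with pytest.raises(ValueError):
            reconstruct_confusion_matrices({"m": (0.99, 0.99), "x": (0.33, 0.77)}, 6)
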