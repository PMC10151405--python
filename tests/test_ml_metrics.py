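"""Metric definitions against brute-force oracles; tuning-loop behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grainpred import (ConfusionCounts, ModelSpec, accuracy, auc,
                       confusion_counts, f1, pearson, tune_fit)
from grainpred.metrics import UndefinedMetricError

from oracles import auc_pairwise


class TestConfusionMetrics:
    @pytest.mark.parametrize("c,expected", [
        (ConfusionCounts(10, 10, 0, 0), 1.0),
        (ConfusionCounts(9, 9, 1, 1), 0.9),
        (ConfusionCounts(0, 0, 5, 5), 0.0),
    ])
    def test_accuracy_values(self, c, expected):
        assert accuracy(c) == pytest.approx(expected)

    @pytest.mark.parametrize("c,expected", [
        (ConfusionCounts(5, 5, 0, 0), 1.0),
        (ConfusionCounts(8, 0, 2, 2), 0.8),
        (ConfusionCounts(0, 4, 3, 3), 0.0),
    ])
    def test_f1_values(self, c, expected):
        assert f1(c) == pytest.approx(expected)

    def test_undefined_cases_raise(self):
        with pytest.raises(UndefinedMetricError):
            accuracy(ConfusionCounts(0, 0, 0, 0))
        with pytest.raises(UndefinedMetricError):
            f1(ConfusionCounts(0, 5, 0, 0))

    def test_counts_from_labels(self):
        c = confusion_counts([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 1, 1)
        assert c.total == 5

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20),
           st.integers(0, 20))
    def test_metrics_bounded(self, tp, tn, fp, fn):
        c = ConfusionCounts(tp, tn, fp, fn)
        if c.total:
            assert 0 <= accuracy(c) <= 1
        if tp + fp + fn:
            assert 0 <= f1(c) <= 1


class TestAuc:
    def test_perfect_and_tied_toy_matches_pairwise_oracle(self):
        labels = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([0.9, 0.8, 0.5, 0.5, 0.3, 0.1])  # one cross-class tie
        assert auc(scores, labels) == pytest.approx(auc_pairwise(scores, labels))
        assert auc(labels.astype(float), labels) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=4000)
        scores = rng.random(4000)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.standard_normal(50)
        assert auc(scores, labels) == pytest.approx(
            auc(np.exp(scores), labels))

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.1, 0.2], [1, 1])

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_always_matches_pairwise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        scores = rng.integers(0, 4, size=n).astype(float)  # force ties
        assert auc(scores, labels) == pytest.approx(
            auc_pairwise(scores, labels), abs=1e-12)


class TestPearson:
    def test_exact_values(self):
        assert pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9819805061)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        assert pearson(2.5 * a + 1, b) == pytest.approx(pearson(a, b))

    def test_constant_vector_returns_nan(self):
        assert np.isnan(pearson([1.0, 1.0, 1.0], [1, 2, 3]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])


class TestTuneFit:
    def test_grid_of_one_is_plain_fit(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 3))
        y = (X[:, 0] > 0).astype(int)
        spec = ModelSpec("random_forest",
                         grid={"n_estimators": [50], "max_features": ["sqrt"]})
        est, best = tune_fit(spec, X, y, seed=0)
        assert best == {"n_estimators": 50, "max_features": "sqrt"}

    def test_separable_classes_fit_perfectly(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.standard_normal((20, 2)) + 5,
                       rng.standard_normal((20, 2)) - 5])
        y = np.r_[np.ones(20), np.zeros(20)]
        spec = ModelSpec("svm_rbf", grid={"C": [1.0], "gamma_scale": [1.0]})
        est, _ = tune_fit(spec, X, y, seed=0)
        assert accuracy(confusion_counts(y, est.predict(X))) == 1.0

    def test_single_class_labels_rejected(self):
        spec = ModelSpec("logistic")
        with pytest.raises(ValueError):
            tune_fit(spec, np.zeros((10, 2)), np.ones(10))

    def test_rf_regression_recovers_signal_out_of_fold(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 4))
        y = X[:, 0] + 0.2 * rng.standard_normal(200)
        spec = ModelSpec("rf_regress",
                         grid={"n_estimators": [200], "max_features": [1.0]})
        est, _ = tune_fit(spec, X[:150], y[:150], seed=0)
        assert pearson(y[150:], est.predict(X[150:])) > 0.8

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((60, 5))
        y = (X[:, 0] + 0.5 * rng.standard_normal(60) > 0).astype(int)
        spec = ModelSpec("random_forest",
                         grid={"n_estimators": [50], "max_features": ["sqrt", 1.0]})
        _, b1 = tune_fit(spec, X, y, seed=42)
        _, b2 = tune_fit(spec, X, y, seed=42)
        assert b1 == b2
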