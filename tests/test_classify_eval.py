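"""Shallow classifiers, metric suite, cross-validation, t-test."""

import numpy as np
import pytest

from planefusion.classify_eval import (
    ClassifierSpec,
    ShallowNeuralNetClassifier,
    _metrics_from_predictions,
    critical_t,
    evaluate,
    kfold_cv,
    paired_diff_ttest,
    train_shallow_nn,
)
from planefusion.train_extract import DataError, FeatureMatrix


def separable_features(n_per_class=40, k=2, width=6, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_per_class * k, width))
    y = np.repeat(np.arange(k), n_per_class)
    for c in range(k):
        X[y == c, c % width] += gap * (c + 1)
    return FeatureMatrix(X, y, [f"c{c}" for c in range(k)])


class TestShallowNN:
    def test_beats_nearest_centroid_on_separable_data(self):
        fm = separable_features()
        train, test = np.arange(0, 80, 2), np.arange(1, 80, 2)
        clf = ShallowNeuralNetClassifier("narrow", seed=0).fit(
            fm.values[train], fm.labels[train]
        )
        acc = clf.score(fm.values[test], fm.labels[test])
        # oracle baseline: nearest centroid
        cents = np.stack(
            [fm.values[train][fm.labels[train] == c].mean(axis=0) for c in (0, 1)]
        )
        d2 = ((fm.values[test][:, None] - cents[None]) ** 2).sum(-1)
        baseline = np.mean(np.argmin(d2, axis=1) == fm.labels[test])
        assert acc > 0.9
        assert acc >= baseline - 1e-9

    def test_same_seed_same_predictions(self):
        fm = separable_features(seed=3)
        preds = [
            ShallowNeuralNetClassifier("medium", seed=9)
            .fit(fm.values, fm.labels)
            .predict(fm.values)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_trilayered_reports_three_hidden_layers(self):
        fm = separable_features()
        clf = train_shallow_nn(ClassifierSpec(family="trilayered", seed=0), fm)
        assert clf.n_hidden_layers_ == 3

    def test_family_layout_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(family="narrow", hidden=(25,))

    def test_single_class_rejected(self):
        fm = separable_features()
        with pytest.raises(DataError):
            ShallowNeuralNetClassifier().fit(fm.values, np.zeros(len(fm.values)))


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.repeat(np.arange(3), 10)
        score = np.eye(3)[y]
        rep = _metrics_from_predictions(y, y, score, np.arange(3))
        assert rep.accuracy == 100.0
        assert rep.f1 == pytest.approx(100.0)
        assert rep.mcc == pytest.approx(1.0)
        assert rep.kappa == pytest.approx(1.0)
        assert rep.fnr == pytest.approx(0.0)
        assert rep.auc == pytest.approx(1.0)

    def test_label_independent_predictions_have_near_zero_kappa(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 4, size=10_000)
        pred = rng.integers(0, 4, size=10_000)
        rep = _metrics_from_predictions(y, pred, None, np.arange(4))
        assert abs(rep.kappa) < 0.05
        assert abs(rep.mcc) < 0.05

    def test_anti_diagonal_binary_confusion_gives_mcc_minus_one(self):
        y = np.repeat([0, 1], 50)
        pred = 1 - y
        rep = _metrics_from_predictions(y, pred, None, np.arange(2))
        assert rep.mcc == pytest.approx(-1.0)

    def test_fnr_complements_macro_recall(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 3, 300)
        pred = rng.integers(0, 3, 300)
        rep = _metrics_from_predictions(y, pred, None, np.arange(3))
        assert rep.fnr == pytest.approx(100.0 - rep.recall, abs=1e-9)

    def test_macro_metrics_invariant_to_class_relabeling(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 3, 500)
        pred = rng.integers(0, 3, 500)
        rep = _metrics_from_predictions(y, pred, None, np.arange(3))
        perm = np.array([2, 0, 1])
        rep_p = _metrics_from_predictions(perm[y], perm[pred], None, np.arange(3))
        assert rep.recall == pytest.approx(rep_p.recall)
        assert rep.precision == pytest.approx(rep_p.precision)
        assert rep.f1 == pytest.approx(rep_p.f1)

    def test_evaluate_populates_from_fitted_classifier(self):
        fm = separable_features()
        clf = ShallowNeuralNetClassifier("narrow", seed=0).fit(fm.values, fm.labels)
        rep = evaluate(clf, fm)
        assert rep.confusion.sum() == len(fm.labels)
        assert 0 <= rep.auc <= 1


class TestKFold:
    def test_folds_partition_indices(self):
        fm = separable_features(n_per_class=15)
        rep = kfold_cv(ClassifierSpec(family="narrow", seed=0), fm, k=5, seed=0)
        assert rep.confusion.sum() == len(fm.labels)

    def test_leave_one_out_when_k_equals_n(self):
        fm = separable_features(n_per_class=10)
        rep = kfold_cv(ClassifierSpec(family="narrow", seed=0), fm, k=10, seed=1)
        assert rep.confusion.sum() == 20

    def test_k_reduced_to_smallest_class(self, caplog):
        fm = separable_features(n_per_class=3)
        rep = kfold_cv(ClassifierSpec(family="narrow", seed=0), fm, k=5, seed=0)
        assert rep.confusion.sum() == 6

    def test_k_above_n_rejected(self):
        fm = separable_features(n_per_class=2)
        with pytest.raises(DataError):
            kfold_cv(ClassifierSpec(), fm, k=50, seed=0)

    def test_pooled_accuracy_on_separable_data(self):
        fm = separable_features(n_per_class=30)
        rep = kfold_cv(ClassifierSpec(family="narrow", seed=0), fm, k=5, seed=0)
        assert rep.accuracy >= 90.0


class TestTTest:
    def test_identical_vectors_not_significant(self):
        v = np.array([90.0, 91.0, 92.0])
        rep = paired_diff_ttest(v, v)
        assert rep.mu == 0.0 and rep.degenerate and not rep.significant

    def test_closed_form_recomputation_full_precision(self):
        rng = np.random.default_rng(0)
        high = rng.uniform(90, 99, 8)
        low = rng.uniform(85, 95, 8)
        rep = paired_diff_ttest(high, low)
        d = np.abs(high - low)
        t_oracle = np.sqrt(8) * d.mean() / d.std(ddof=1)
        assert rep.t_full == pytest.approx(t_oracle, abs=1e-10)
        assert rep.df == 7

    def test_interval_is_symmetric_pm_critical(self):
        rep = paired_diff_ttest(np.array([1.0, 2.0, 4.0]), np.array([0.5, 1.0, 2.0]), alpha=0.1)
        lo, hi = rep.interval
        assert lo == -hi
        assert hi == pytest.approx(critical_t(0.1, 2))

    def test_length_mismatch_and_short_input_rejected(self):
        with pytest.raises(ValueError):
            paired_diff_ttest(np.array([1.0, 2.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            paired_diff_ttest(np.array([1.0]), np.array([1.0]))


class TestCriticalT:
    def test_normal_limit(self):
        assert critical_t(0.05, 10**6) == pytest.approx(1.960, abs=1e-3)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            critical_t(0.0, 4)
        with pytest.raises(ValueError):
            critical_t(0.05, 0)
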