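"""IGNDO feature selection, thresholding, and serial fusion."""

import numpy as np
import pytest

from planefusion.gndo import GNDOConfig
from planefusion.selection import (
    FitnessSpec,
    IGNDOSelector,
    compute_cross_entropy,
    igndo_select,
    position_to_scores,
    serial_fuse,
    threshold_select,
)
from planefusion.train_extract import DataError, FeatureMatrix


class TestScoreMap:
    def test_logistic_values(self):
        np.testing.assert_allclose(position_to_scores(np.array([0.0])), [0.5])
        assert position_to_scores(np.array([10.0]))[0] == pytest.approx(0.9999546, abs=1e-6)
        s = position_to_scores(np.array([-3.0, 0.0, 3.0]))
        assert np.all(np.diff(s) > 0)  # monotone
        assert np.all((s > 0) & (s < 1))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            position_to_scores(np.array([np.inf]))


class TestCrossEntropy:
    def test_half_scores_give_ln2(self):
        assert compute_cross_entropy(np.full(7, 0.5)) == pytest.approx(np.log(2), abs=1e-12)

    def test_direct_formula(self):
        # scores (0.9, 0.1): both terms are -log 0.9
        assert compute_cross_entropy(np.array([0.9, 0.1])) == pytest.approx(
            -np.log(0.9), abs=1e-12
        )

    def test_confident_scores_drive_ce_to_zero(self):
        eps = 1e-12
        ce = compute_cross_entropy(np.array([eps, 1 - eps, eps]))
        assert 0 <= ce < 1e-10

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            compute_cross_entropy(np.array([]))


class TestThreshold:
    def test_direct_selection(self):
        res = threshold_select(np.array([0.9, 0.2, 0.7]), 0.6)
        np.testing.assert_array_equal(res.mask, [True, False, True])
        assert res.selected_width == 2
        np.testing.assert_array_equal(res.selected_indices, [0, 2])

    def test_all_below_falls_back_to_half_rule(self, caplog):
        res = threshold_select(np.array([0.6, 0.3]), 0.95)
        np.testing.assert_array_equal(res.mask, [True, False])

    def test_zero_threshold_selects_everything(self):
        res = threshold_select(np.array([0.1, 0.9, 0.4]), 0.0)
        assert res.selected_width == 3

    def test_idempotent_on_binarized_scores(self):
        eps = 1e-12
        scores = np.array([1 - eps, eps, 1 - eps, eps])
        first = threshold_select(scores, compute_cross_entropy(scores))
        second = threshold_select(first.scores, compute_cross_entropy(first.scores))
        np.testing.assert_array_equal(first.mask, second.mask)


class TestIGNDOSelect:
    def test_label_leak_column_always_selected(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((120, 20))
        y = np.arange(120) % 2
        X[:, 7] = y
        fm = FeatureMatrix(X, y, ["a", "b"])
        for seed in range(3):
            res = igndo_select(
                fm, FitnessSpec(seed=seed), GNDOConfig(20, 30, seed=seed)
            )
            assert 7 in res.selected_indices
        # oracle: exhaustive single-feature scan ranks column 7 best
        from planefusion.selection import _NearestCentroidFitness

        fit = _NearestCentroidFitness(X, y, FitnessSpec(seed=0))
        errors = [
            fit.error(np.eye(20, dtype=bool)[j]) for j in range(20)
        ]
        assert int(np.argmin(errors)) == 7

    def test_zero_iterations_still_yields_valid_result(self, planted300):
        fm, _ = planted300
        res = igndo_select(fm, FitnessSpec(seed=0), GNDOConfig(20, 0, seed=0))
        assert res.selected_width >= 1
        assert res.mask.shape == (fm.width,)

    def test_single_class_rejected(self):
        fm = FeatureMatrix(np.random.default_rng(0).random((10, 5)), np.zeros(10, int), ["a"])
        with pytest.raises(DataError):
            igndo_select(fm, FitnessSpec(), GNDOConfig(5, 2, seed=0))

    def test_mask_never_empty(self, planted300):
        fm, _ = planted300
        for seed in range(3):
            res = igndo_select(fm, FitnessSpec(seed=seed), GNDOConfig(6, 5, seed=seed))
            assert res.selected_width >= 1


class TestSerialFuse:
    def _block(self, n, width, seed, labels=None):
        rng = np.random.default_rng(seed)
        labels = labels if labels is not None else np.arange(n) % 2
        return FeatureMatrix(rng.random((n, width)), labels, ["a", "b"])

    def test_width_adds_and_order_preserved(self):
        a, b = self._block(20, 5, 0), self._block(20, 3, 1)
        fused = serial_fuse(a, b)
        assert fused.width == 8
        np.testing.assert_array_equal(fused.values[:, :5], a.values)
        np.testing.assert_array_equal(fused.values[:, 5:], b.values)
        np.testing.assert_array_equal(fused.labels, a.labels)

    def test_zero_width_block_is_identity(self):
        a = self._block(10, 4, 0)
        empty = FeatureMatrix(np.zeros((10, 0)), a.labels, ["a", "b"])
        np.testing.assert_array_equal(serial_fuse(a, empty).values, a.values)

    def test_width_is_associative(self):
        a, b, c = self._block(8, 2, 0), self._block(8, 3, 1), self._block(8, 4, 2)
        assert serial_fuse(serial_fuse(a, b), c).width == 2 + 3 + 4

    def test_row_and_label_mismatches_rejected(self):
        a = self._block(10, 4, 0)
        with pytest.raises(DataError):
            serial_fuse(a, self._block(11, 4, 1))
        flipped = self._block(10, 4, 1, labels=(np.arange(10) + 1) % 2)
        with pytest.raises(DataError):
            serial_fuse(a, flipped)


def test_selector_estimator_interface(planted300):
    fm, truth = planted300
    sel = IGNDOSelector(population_size=10, max_iterations=10, seed=0)
    Xt = sel.fit_transform(fm.values, fm.labels)
    assert Xt.shape == (fm.values.shape[0], sel.n_features_selected_)
    assert sel.get_support().sum() == sel.n_features_selected_
    assert 0 < sel.threshold_
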