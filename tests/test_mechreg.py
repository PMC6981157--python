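import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from callusmech.imageproc import (
    LABEL_BACKGROUND,
    LABEL_FORMATION,
    LABEL_QUIESCENCE,
    LABEL_RESORPTION,
    OverlayLabels,
)
from callusmech.mechreg import (
    STATE_FORMATION,
    STATE_QUIESCENCE,
    STATE_RESORPTION,
    SurfaceStateMap,
    ThresholdPair,
    ccr_heatmap,
    classify_surface,
    confusion_ccr,
    extract_surface_states,
    roc_analysis,
)


def _labels_from_flat(pos, neg, n_side=None):
    """Build a degenerate overlay volume whose first voxels carry the labels."""
    n = pos.size
    side = int(np.ceil(n ** (1 / 3))) + 1
    vol = np.full(side**3, LABEL_QUIESCENCE, np.uint8)
    vol[:n] = np.where(pos, LABEL_FORMATION, LABEL_BACKGROUND)
    return OverlayLabels(vol.reshape(side, side, side), threshold=395.0)


def _signal_volume(signal, shape):
    vol = np.zeros(int(np.prod(shape)))
    vol[: signal.size] = signal
    return vol.reshape(shape)


def mann_whitney_auc(s_pos, s_neg):
    """Brute-force pairwise oracle: P(S+ > S-) + 0.5 P(S+ = S-)."""
    diff = s_pos[:, None] - s_neg[None, :]
    return (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (s_pos.size * s_neg.size)


class TestROC:
    def _run(self, signal, positive):
        labels = _labels_from_flat(positive, ~positive)
        vol = _signal_volume(signal, labels.shape)
        mask = np.zeros(labels.shape, bool)
        mask.ravel()[: signal.size] = True
        return roc_analysis(vol, labels, mask)

    def test_perfect_separation(self):
        rng = np.random.default_rng(0)
        signal = np.r_[rng.uniform(0.5, 1.0, 100), rng.uniform(0.0, 0.4, 150)]
        positive = np.r_[np.ones(100, bool), np.zeros(150, bool)]
        roc = self._run(signal, positive)
        assert roc.auc == pytest.approx(1.0)
        assert roc.tpr_opt == 1.0
        assert roc.fpr_opt == 0.0

    def test_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(42)
        n = 2000
        signal = np.round(rng.normal(size=n), 2)  # rounding forces ties
        positive = rng.random(n) < 0.4
        positive[0] = True
        positive[1] = False
        roc = self._run(signal, positive)
        oracle = mann_whitney_auc(signal[positive], signal[~positive])
        assert roc.auc == pytest.approx(oracle, abs=1e-12)

    def test_null_association_auc_near_half(self):
        rng = np.random.default_rng(7)
        n = 2000
        signal = rng.normal(size=n)
        positive = rng.random(n) < 0.5  # independent of signal
        roc = self._run(signal, positive)
        assert 0.45 <= roc.auc <= 0.55

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        n = 500
        signal = rng.normal(size=n)
        positive = signal + rng.normal(scale=0.5, size=n) > 0
        if positive.all() or not positive.any():
            positive[:2] = [True, False]
        base = self._run(signal, positive).auc
        assert self._run(np.exp(signal), positive).auc == pytest.approx(base, abs=1e-12)
        assert self._run(3.0 * signal + 10.0, positive).auc == pytest.approx(base, abs=1e-12)

    def test_optimal_point_maximises_youden(self):
        signal = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        positive = np.array([False, False, False, True, True, True])
        roc = self._run(signal, positive)
        assert roc.t_opt == pytest.approx(0.4)
        assert roc.youden == pytest.approx(1.0)

    def test_empty_class_fails(self):
        signal = np.array([0.1, 0.2])
        positive = np.array([True, True])
        with pytest.raises(ValueError):
            self._run(signal, positive)

    def test_resorbed_voxels_excluded_from_candidates(self):
        vol = np.full((3, 3, 3), LABEL_BACKGROUND, np.uint8)
        vol[0, 0, 0] = LABEL_RESORPTION
        vol[0, 0, 1] = LABEL_QUIESCENCE
        vol[0, 0, 2] = LABEL_FORMATION
        labels = OverlayLabels(vol, threshold=395.0)
        roc = roc_analysis(np.random.default_rng(0).random((3, 3, 3)), labels)
        assert roc.n_pos == 1
        # 27 voxels minus R and Q (not candidates) minus the one positive
        assert roc.n_neg == 24


class TestSurfaceStates:
    @staticmethod
    def _ov(label_vol):
        return OverlayLabels(label_vol.astype(np.uint8), threshold=395.0)

    def test_isolated_surviving_voxel_is_quiescent(self):
        vol = np.full((3, 3, 3), LABEL_BACKGROUND)
        vol[1, 1, 1] = LABEL_QUIESCENCE
        surf = extract_surface_states(self._ov(vol))
        assert len(surf) == 1
        assert surf.states[0] == STATE_QUIESCENCE

    def test_isolated_removed_voxel_is_resorption(self):
        vol = np.full((3, 3, 3), LABEL_BACKGROUND)
        vol[1, 1, 1] = LABEL_RESORPTION
        surf = extract_surface_states(self._ov(vol))
        assert len(surf) == 1
        assert surf.states[0] == STATE_RESORPTION

    def test_formation_precedence_over_quiescence(self):
        # Q voxel with both an F face-neighbour and a B face-neighbour
        vol = np.full((3, 3, 3), LABEL_BACKGROUND)
        vol[1, 1, 1] = LABEL_QUIESCENCE
        vol[1, 1, 2] = LABEL_FORMATION
        surf = extract_surface_states(self._ov(vol))
        states = dict(zip(map(tuple, surf.indices), surf.states))
        assert states[(1, 1, 1)] == STATE_FORMATION

    def test_diagonal_neighbours_do_not_count(self):
        vol = np.full((3, 3, 3), LABEL_BACKGROUND)
        vol[1, 1, 1] = LABEL_QUIESCENCE
        vol[2, 2, 2] = LABEL_FORMATION  # 26- but not 6-adjacent
        surf = extract_surface_states(self._ov(vol))
        states = dict(zip(map(tuple, surf.indices), surf.states))
        assert states[(1, 1, 1)] == STATE_QUIESCENCE

    def test_empty_bone_warns(self):
        vol = np.full((3, 3, 3), LABEL_BACKGROUND)
        with pytest.warns(UserWarning):
            surf = extract_surface_states(self._ov(vol))
        assert len(surf) == 0

    def test_signal_sampling_at_bone_voxel(self):
        vol = np.full((3, 3, 3), LABEL_BACKGROUND)
        vol[1, 1, 1] = LABEL_QUIESCENCE
        eff = np.zeros((3, 3, 3))
        eff[1, 1, 1] = 0.7
        surf = extract_surface_states(self._ov(vol), eff)
        assert surf.signal[0] == pytest.approx(0.7)

    def test_signal_sampling_soft_neighbours(self):
        vol = np.full((3, 3, 3), LABEL_BACKGROUND)
        vol[1, 1, 1] = LABEL_QUIESCENCE
        eff = np.ones((3, 3, 3)) * 0.2
        eff[1, 1, 1] = 0.7
        surf = extract_surface_states(self._ov(vol), eff, sample="soft")
        assert surf.signal[0] == pytest.approx(0.2)


class TestClassifier:
    def _map(self, signal, states=None):
        n = signal.size
        if states is None:
            states = np.zeros(n, np.int64)
        return SurfaceStateMap(
            indices=np.zeros((n, 3), np.int64), states=states, signal=signal
        )

    def test_midband_is_quiescence(self):
        pair = ThresholdPair(0.2, 0.6)
        pred = classify_surface(self._map(np.array([0.4])), pair)
        assert pred[0] == STATE_QUIESCENCE

    def test_boundaries_fall_in_quiescence(self):
        pair = ThresholdPair(0.2, 0.6)
        pred = classify_surface(self._map(np.array([0.2, 0.6])), pair)
        assert np.all(pred == STATE_QUIESCENCE)

    def test_all_formation_when_tf_below_signals(self):
        pair = ThresholdPair(0.0, 0.01)
        pred = classify_surface(self._map(np.array([0.5, 0.9, 0.02])), pair)
        assert np.all(pred == STATE_FORMATION)

    def test_infinite_band_all_quiescence(self):
        pair = ThresholdPair(-np.inf, np.inf)
        pred = classify_surface(self._map(np.array([-5.0, 0.0, 5.0])), pair)
        assert np.all(pred == STATE_QUIESCENCE)

    def test_pair_validation(self):
        with pytest.raises(ValueError):
            ThresholdPair(0.5, 0.5)


class TestConfusion:
    def test_identity_for_perfect_prediction(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        cm = confusion_ccr(truth, truth)
        np.testing.assert_allclose(cm.matrix, np.eye(3))
        assert cm.ccr == 1.0

    def test_constant_quiescence_prediction(self):
        truth = np.array([0, 1, 2, 0, 1, 2])
        pred = np.full(6, STATE_QUIESCENCE)
        cm = confusion_ccr(pred, truth)
        assert cm.ccr == pytest.approx(1.0 / 3.0)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 3, 300)
        pred = rng.integers(0, 3, 300)
        cm = confusion_ccr(pred, truth)
        np.testing.assert_allclose(cm.matrix.sum(axis=0), 1.0)

    def test_random_prediction_ccr_third(self):
        rng = np.random.default_rng(5)
        n = 10_000
        truth = rng.integers(0, 3, n)
        pred = rng.integers(0, 3, n)
        cm = confusion_ccr(pred, truth)
        # binomial bound: each diagonal entry ~ Binomial(n_j, 1/3) / n_j
        sigma = 3 * np.sqrt((1 / 3) * (2 / 3) / (n / 3))
        assert abs(cm.ccr - 1 / 3) <= sigma

    def test_empty_category_flagged(self):
        truth = np.array([0, 0, 1])
        pred = np.array([0, 1, 1])
        cm = confusion_ccr(pred, truth)
        assert "resorption" in cm.empty_categories

    def test_all_empty_fails(self):
        with pytest.raises(ValueError):
            confusion_ccr(np.array([], dtype=int), np.array([], dtype=int))

    def test_duplication_invariance(self):
        rng = np.random.default_rng(9)
        truth = rng.integers(0, 3, 200)
        pred = rng.integers(0, 3, 200)
        base = confusion_ccr(pred, truth)
        doubled = confusion_ccr(np.r_[pred, pred], np.r_[truth, truth])
        assert doubled.ccr == pytest.approx(base.ccr, abs=1e-15)
        np.testing.assert_allclose(doubled.matrix, base.matrix)


class TestHeatmap:
    @staticmethod
    def _synthetic_map(n, t_r, t_f, noise, seed):
        rng = np.random.default_rng(seed)
        signal = rng.uniform(0, 1, n)
        states = np.full(n, STATE_QUIESCENCE, np.int64)
        states[signal > t_f] = STATE_FORMATION
        states[signal < t_r] = STATE_RESORPTION
        if noise > 0:
            flip = rng.random(n) < noise
            states[flip] = rng.integers(0, 3, int(flip.sum()))
        return SurfaceStateMap(
            indices=np.zeros((n, 3), np.int64), states=states, signal=signal
        )

    def test_noise_free_truth_recovered(self):
        surf = self._synthetic_map(800, 0.3, 0.7, 0.0, seed=1)
        # realisable truth: the grid brackets the generative pair
        grid = np.r_[np.linspace(0.0, 1.0, 62), 0.3, 0.7]
        hm = ccr_heatmap(surf, grid=grid)
        assert hm.max_ccr == pytest.approx(1.0)
        assert 0.0 <= hm.best_pair.t_r <= 0.3 + 1e-9
        assert hm.best_pair.t_f <= 0.7 + 1e-9

    def test_matches_bruteforce_exactly(self):
        surf = self._synthetic_map(500, 0.25, 0.6, 0.2, seed=2)
        grid = np.quantile(surf.signal, np.linspace(0, 1, 64))
        hm = ccr_heatmap(surf, grid=grid)
        # independent exhaustive double loop
        thresholds = np.unique(grid)
        best_ccr, best_pair = -np.inf, None
        for i, tr in enumerate(thresholds):
            for j, tf in enumerate(thresholds):
                if not tr < tf:
                    assert np.isnan(hm.ccr[i, j])
                    continue
                pred = classify_surface(surf, ThresholdPair(tr, tf))
                ccr = confusion_ccr(pred, surf.states).ccr
                assert hm.ccr[i, j] == ccr  # exact equality
                if ccr > best_ccr:
                    best_ccr, best_pair = ccr, (tr, tf)
        assert hm.max_ccr == best_ccr
        assert (hm.best_pair.t_r, hm.best_pair.t_f) == best_pair

    def test_no_overlapping_pairs(self):
        surf = self._synthetic_map(200, 0.3, 0.7, 0.1, seed=3)
        hm = ccr_heatmap(surf, grid=32)
        tr = hm.t_r_grid[:, None]
        tf = hm.t_f_grid[None, :]
        assert np.all(np.isnan(hm.ccr[tr >= tf]))
        assert hm.best_pair.t_r < hm.best_pair.t_f

    def test_empty_map_fails(self):
        surf = SurfaceStateMap(
            indices=np.empty((0, 3), np.int64),
            states=np.empty(0, np.int64),
            signal=np.empty(0),
        )
        with pytest.raises(ValueError):
            ccr_heatmap(surf)


class TestPositiveSetNesting:
    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=10, deadline=None)
    def test_positives_nest_across_thresholds(self, seed):
        """Formation at a higher density threshold is a subset of formation
        at a lower one, for the same frame pair."""
        from callusmech.imageproc import BinaryMask, DensityImage, ThresholdLadder, apply_ladder, overlay

        rng = np.random.default_rng(seed)
        img0 = DensityImage(rng.uniform(0, 900, (6, 6, 6)))
        img1 = DensityImage(rng.uniform(0, 900, (6, 6, 6)))
        lad = ThresholdLadder()
        m0 = apply_ladder(img0, lad)
        m1 = apply_ladder(img1, lad)
        f_low = overlay(m0[0], m1[0]).formation
        f_high = overlay(m0[-1], m1[-1]).formation
        # positives at tau_high form a subset of bone-at-t1 at tau_low
        bone_low_t1 = m1[-1].values
        assert np.all(~f_high | bone_low_t1)
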