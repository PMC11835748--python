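import numpy as np
import pytest

import statesync as ss
from statesync.hmm_core import StatePathSet
from statesync.synchrony import empirical_transmat


class TestWindowedConsistency:
    def test_identical_paths_give_100_percent(self):
        path = np.tile([0, 1, 1, 2], 5)
        ps = StatePathSet(np.tile(path, (6, 1)), K=3)
        curve = ss.windowed_consistency(ps, w=3)
        occupied = curve.values.max(axis=0)
        np.testing.assert_array_equal(occupied, 100.0)

    def test_window_arithmetic_two_subjects(self):
        # subject 0 visits state 0 only at volume 10; subject 1 never does
        T = 30
        p0 = np.ones(T, dtype=int)
        p0[10] = 0
        p1 = np.full(T, 2)
        ps = StatePathSet(np.stack([p0, p1]), K=3)
        curve = ss.windowed_consistency(ps, w=3)
        state0 = curve.values[0]
        assert (state0[7:14] == 50.0).all()
        assert (state0[:7] == 0).all() and (state0[14:] == 0).all()

    def test_zero_window_is_instantaneous_share(self):
        ps = StatePathSet(np.array([[0, 1], [0, 0]]), K=2)
        curve = ss.windowed_consistency(ps, w=0)
        np.testing.assert_array_equal(curve.values[0], [100.0, 50.0])

    def test_monotone_in_window_width(self, small_cohort):
        _, paths = small_cohort
        ps = StatePathSet(paths, K=3)
        prev = ss.windowed_consistency(ps, w=0).values
        for w in (1, 2, 4):
            cur = ss.windowed_consistency(ps, w=w).values
            assert (cur >= prev - 1e-12).all()
            prev = cur

    def test_bounded_and_empty_members_rejected(self, small_cohort):
        _, paths = small_cohort
        ps = StatePathSet(paths, K=3)
        curve = ss.windowed_consistency(ps, w=3)
        assert curve.values.min() >= 0 and curve.values.max() <= 100
        with pytest.raises(ValueError, match="empty"):
            ss.windowed_consistency(ps, members=[])


class TestBetweenGroupNull:
    def test_single_iteration_equals_that_pseudo_group_curve(self, small_cohort):
        _, paths = small_cohort
        ps = StatePathSet(paths, K=3)
        seed = 21
        surfaces = ss.between_group_null(ps, (4, 6), n_iter=1, seed=seed)
        perm = np.random.default_rng(seed).permutation(10)
        c_a = ss.windowed_consistency(ps, perm[:4], w=3).values
        c_b = ss.windowed_consistency(ps, perm[4:], w=3).values
        np.testing.assert_allclose(surfaces[4], c_a, atol=1e-6)
        np.testing.assert_allclose(surfaces[6], c_b, atol=1e-6)

    def test_size_mismatch_rejected(self, small_cohort):
        _, paths = small_cohort
        ps = StatePathSet(paths, K=3)
        with pytest.raises(ValueError, match="partition"):
            ss.between_group_null(ps, (4, 4), n_iter=2, seed=0)

    def test_planted_group_exceeds_surface_in_window(self, small_truth):
        plant = ss.PlantedSync(group="A", state=1, windows=[(80, 110)], adherence=1.0)
        cohort, paths = ss.simulate_cohort(small_truth, (6, 7), T=200,
                                           planted=[plant], seed=8)
        ps = StatePathSet(paths, K=3, group_labels=cohort.group_labels)
        idx_a = cohort.group_indices("A")
        curve = ss.windowed_consistency(ps, idx_a, w=3)
        surf = ss.between_group_null(ps, (6, 7), n_iter=200, seed=9)[6]
        # the observed planted-group curve is at ceiling inside the window
        assert (curve.values[1, 85:105] >= surf[1, 85:105]).all()
        assert (curve.values[1, 85:105] == 100.0).all()


class TestWithinGroupNull:
    def test_iid_uniform_chain_matches_window_coverage_oracle(self):
        # K=2 i.i.d. uniform chain: P(state in a window of length L) = 1 - 0.5^L
        K, T, n_subj = 2, 300, 20
        rng = np.random.default_rng(4)
        ps = StatePathSet(rng.integers(0, K, size=(n_subj, T)), K=K)
        thr = ss.within_group_null(ps, n_iter=300, seed=5, w=3)
        w = 3
        lengths = np.minimum(np.arange(T) + w, T - 1) - np.maximum(np.arange(T) - w, 0) + 1
        expect = 100 * (1 - 0.5 ** lengths).mean()
        # 95th percentile of a concentrated null sits just above the mean
        assert thr.shape == (K,)
        np.testing.assert_allclose(thr, expect, atol=1.5)

    def test_null_threshold_ignores_cross_subject_alignment(self, small_truth):
        plant = ss.PlantedSync(group="A", state=0, windows=[(50, 80)], adherence=1.0)
        cohort, paths = ss.simulate_cohort(small_truth, (8, 8), T=200,
                                           planted=[plant], seed=6)
        idx_a = cohort.group_indices("A")
        ps_plant = StatePathSet(paths[idx_a], K=3)
        _, paths2 = ss.simulate_cohort(small_truth, (8, 8), T=200, seed=6)
        ps_plain = StatePathSet(paths2[idx_a], K=3)
        t1 = ss.within_group_null(ps_plant, n_iter=200, seed=7)
        t2 = ss.within_group_null(ps_plain, n_iter=200, seed=7)
        # surrogate paths destroy alignment: thresholds shift only via the
        # (slightly) different empirical transition matrices
        assert np.abs(t1 - t2).max() < 10.0

    def test_seeded_determinism(self, small_cohort):
        _, paths = small_cohort
        ps = StatePathSet(paths[:5], K=3)
        t1 = ss.within_group_null(ps, n_iter=50, seed=10)
        t2 = ss.within_group_null(ps, n_iter=50, seed=10)
        np.testing.assert_array_equal(t1, t2)

    def test_empirical_transmat_degenerate_row_flagged(self):
        paths = np.array([[0, 0, 0, 0]])
        tm, defined = empirical_transmat(paths, K=2)
        assert defined[0] and not defined[1]
        np.testing.assert_array_equal(tm[1], [0, 1])  # self-transition convention


class TestFlagEvents:
    def _setup(self, values, between, within, mask=None):
        K, T = values.shape
        curve = ss.ConsistencyCurve(values=values, window=3, group="A", n_members=5)
        nulls = ss.NullThresholds(between=between, within=within, n_iterations=10)
        if mask is None:
            mask = np.ones(T, bool)
        return curve, nulls, mask

    def test_below_both_thresholds_gives_no_events(self):
        values = np.full((2, 20), 30.0)
        curve, nulls, mask = self._setup(values, np.full((2, 20), 50.0),
                                         np.array([40.0, 40.0]))
        assert ss.flag_sync_events(curve, nulls, mask) == []

    def test_exceeding_only_one_threshold_not_flagged(self):
        values = np.full((1, 10), 60.0)
        # beats within (40) but not between (70)
        curve, nulls, mask = self._setup(values, np.full((1, 10), 70.0),
                                         np.array([40.0]))
        assert ss.flag_sync_events(curve, nulls, mask) == []
        # beats between (50) but not within (80)
        curve, nulls, mask = self._setup(values, np.full((1, 10), 50.0),
                                         np.array([80.0]))
        assert ss.flag_sync_events(curve, nulls, mask) == []

    def test_conjunction_flags_only_masked_volumes(self):
        values = np.zeros((1, 12))
        values[0, 3:9] = 90.0
        mask = np.zeros(12, bool)
        mask[5:20] = True
        curve, nulls, _ = self._setup(values, np.full((1, 12), 50.0),
                                      np.array([40.0]))
        events = ss.flag_sync_events(curve, nulls, mask)
        assert len(events) == 1
        assert (events[0].start, events[0].end) == (5, 9)
        assert events[0].peak == 90.0

    def test_min_run_filters_short_blips(self):
        values = np.zeros((1, 20))
        values[0, 2] = 90.0
        values[0, 10:15] = 90.0
        curve, nulls, mask = self._setup(values, np.full((1, 20), 50.0),
                                         np.array([40.0]))
        events = ss.flag_sync_events(curve, nulls, mask, min_run=3)
        assert [(e.start, e.end) for e in events] == [(10, 15)]

    def test_identical_paths_degenerate_gracefully(self):
        ps = StatePathSet(np.tile(np.tile([0, 1], 50), (6, 1)), K=2)
        curve = ss.windowed_consistency(ps, w=3)
        thr = ss.within_group_null(ps, n_iter=50, seed=1)
        nulls = ss.NullThresholds(between=np.full(curve.values.shape, 95.0),
                                  within=thr, n_iterations=50)
        events = ss.flag_sync_events(curve, nulls, np.ones(100, bool))
        for e in events:
            assert 0 <= e.start < e.end <= 100
            assert 0 <= e.peak <= 100
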