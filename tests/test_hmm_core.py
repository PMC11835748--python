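import numpy as np
import pytest

import statesync as ss
from statesync.hmm_core import (
    HmmFit,
    total_log_likelihood,
    _emission_logprob,
)
from conftest import brute_force_loglik, brute_force_viterbi, random_toy_hmm


def _toy_fit(init, trans, means, covs):
    K = init.shape[0]
    return HmmFit(K=K, means=means, covs=covs, transmat=trans, initial=init,
                  loglik_trace=np.array([0.0]))


class TestForwardLikelihood:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            K = rng.integers(2, 4)
            T = rng.integers(2, 7)
            init, trans, means, covs = random_toy_hmm(rng, K)
            series = rng.normal(0, 2, size=(T, 1))
            fit = _toy_fit(init, trans, means, covs)
            got = ss.log_likelihood(fit, series)
            want = brute_force_loglik(init, trans, means, covs, series)
            assert got == pytest.approx(want, abs=1e-8)

    def test_state_independent_emissions_reduce_to_iid_gaussian(self):
        rng = np.random.default_rng(0)
        K, T = 3, 20
        init = rng.dirichlet(np.ones(K))
        trans = rng.dirichlet(np.ones(K), size=K)
        mean = np.array([0.7])
        means = np.tile(mean, (K, 1))
        covs = np.tile(np.eye(1) * 1.3, (K, 1, 1))
        series = rng.normal(size=(T, 1))
        fit = _toy_fit(init, trans, means, covs)
        iid = _emission_logprob(series, mean[None, :], covs[:1])[:, 0].sum()
        assert ss.log_likelihood(fit, series) == pytest.approx(iid, abs=1e-10)

    def test_subject_boundary_reset_doubles_loglik(self, small_truth):
        rng = np.random.default_rng(1)
        series = rng.normal(size=(50, 5))
        fit = _toy_fit(small_truth.initial, small_truth.transmat,
                       small_truth.state_means, small_truth.state_covs)
        single = ss.log_likelihood(fit, series)
        cohort = ss.CohortSeries(np.stack([series, series]), 0.81,
                                 ["s1", "s2"], [f"r{i}" for i in range(5)],
                                 ["A", "B"])
        assert total_log_likelihood(fit, cohort) == pytest.approx(2 * single, rel=1e-10)

    def test_dimension_mismatch_rejected(self, small_fit):
        with pytest.raises(ValueError, match="regions"):
            ss.log_likelihood(small_fit, np.zeros((10, 2)))


class TestViterbi:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            K = rng.integers(2, 4)
            T = rng.integers(2, 7)
            init, trans, means, covs = random_toy_hmm(rng, K)
            series = rng.normal(0, 2, size=(T, 1))
            fit = _toy_fit(init, trans, means, covs)
            got = ss.viterbi(fit, series)
            want, _ = brute_force_viterbi(init, trans, means, covs, series)
            np.testing.assert_array_equal(got, want)

    def test_separated_emissions_give_nearest_state(self, small_truth):
        # emissions pinned on state means with a near-uniform chain
        K = small_truth.n_states
        series = small_truth.state_means[[0, 2, 1, 1, 0]]
        fit = _toy_fit(np.full(K, 1 / K), np.full((K, K), 1 / K),
                       small_truth.state_means, small_truth.state_covs)
        np.testing.assert_array_equal(ss.viterbi(fit, series), [0, 2, 1, 1, 0])

    def test_exact_tie_returns_lexicographically_smallest(self):
        # identical states everywhere: every path ties, so all-zeros must win
        K = 3
        means = np.zeros((K, 1))
        covs = np.tile(np.eye(1), (K, 1, 1))
        fit = _toy_fit(np.full(K, 1 / K), np.full((K, K), 1 / K), means, covs)
        path = ss.viterbi(fit, np.random.default_rng(3).normal(size=(6, 1)))
        np.testing.assert_array_equal(path, np.zeros(6, dtype=int))


class TestFit:
    def test_loglik_trace_monotone(self, small_fit):
        diffs = np.diff(small_fit.loglik_trace)
        assert (diffs >= -1e-8).all()

    def test_seeded_determinism(self, small_cohort):
        cohort, _ = small_cohort
        f1 = ss.fit_hmm(cohort, 3, n_restarts=2, seed=11)
        f2 = ss.fit_hmm(cohort, 3, n_restarts=2, seed=11)
        np.testing.assert_array_equal(f1.means, f2.means)
        np.testing.assert_array_equal(f1.transmat, f2.transmat)

    def test_parameter_recovery_small(self, small_truth, small_cohort, small_fit):
        cohort, true_paths = small_cohort
        decoded = ss.decode_paths(small_fit, cohort)
        perm = ss.align_states(small_fit, small_truth,
                               decoded_paths=decoded.paths,
                               reference_paths=true_paths)
        agreement = (perm[decoded.paths] == true_paths).mean()
        assert agreement >= 0.9
        inv = np.argsort(perm)
        err = np.abs(small_fit.transmat[np.ix_(inv, inv)] - small_truth.transmat).max()
        assert err <= 0.05

    def test_subject_order_permutation_only_permutes_paths(self, small_cohort):
        cohort, _ = small_cohort
        order = np.array([3, 1, 0, 2, 4, 9, 8, 7, 6, 5])
        shuffled = ss.CohortSeries(cohort.data[order], cohort.tr_seconds,
                                   [cohort.subject_ids[i] for i in order],
                                   cohort.region_ids,
                                   [cohort.group_labels[i] for i in order])
        f1 = ss.fit_hmm(cohort, 3, n_restarts=1, seed=5)
        f2 = ss.fit_hmm(shuffled, 3, n_restarts=1, seed=5)
        # same data multiset -> same likelihood optimum reached
        assert f1.final_loglik == pytest.approx(f2.final_loglik, rel=1e-3)
        p1 = ss.decode_paths(f1, cohort)
        p2 = ss.decode_paths(f2, shuffled)
        perm = ss.align_states(f1, f2, decoded_paths=p1.paths[order],
                               reference_paths=p2.paths)
        assert (perm[p1.paths[order]] == p2.paths).mean() > 0.99

    def test_json_roundtrip(self, small_fit, tmp_path):
        path = tmp_path / "fit.json"
        small_fit.to_json(path)
        back = HmmFit.from_json(path)
        np.testing.assert_array_equal(back.means, small_fit.means)
        np.testing.assert_array_equal(back.transmat, small_fit.transmat)
        assert back.n_params == small_fit.n_params

    def test_cross_check_against_hmmlearn_likelihood(self, small_fit):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(2)
        series = rng.normal(size=(40, 5))
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="full",
                                   init_params="")
        ref.startprob_ = small_fit.initial
        ref.transmat_ = small_fit.transmat
        ref.means_ = small_fit.means
        ref.covars_ = small_fit.covs
        assert ss.log_likelihood(small_fit, series) == pytest.approx(
            ref.score(series), abs=1e-6)


class TestModelSelection:
    def test_aic_formula(self, small_fit, small_cohort):
        cohort, _ = small_cohort
        ll = total_log_likelihood(small_fit, cohort)
        assert ss.aic(small_fit, cohort) == pytest.approx(
            2 * small_fit.n_params - 2 * ll)

    def test_n_params_counts_free_parameters(self, small_fit):
        K, R = 3, 5
        expected = (K - 1) + K * (K - 1) + K * R + K * (R * (R + 1) // 2)
        assert small_fit.n_params == expected

    def test_aic_selects_true_state_count(self, small_cohort):
        cohort, _ = small_cohort
        best, table = ss.select_k(cohort, [2, 3, 4], seed=1, n_restarts=1)
        assert best == 3
        assert len(table) == 3

    def test_singleton_range(self, small_cohort):
        cohort, _ = small_cohort
        best, table = ss.select_k(cohort, [3], seed=0, n_restarts=1)
        assert best == 3 and len(table) == 1


class TestAlignStates:
    def test_identity_alignment(self, small_truth):
        perm = ss.align_states(small_truth, small_truth)
        np.testing.assert_array_equal(perm, np.arange(3))

    def test_permuted_copy_recovers_inverse(self, small_truth):
        import dataclasses
        order = np.array([2, 0, 1])
        permuted = dataclasses.replace(
            small_truth,
            state_means=small_truth.state_means[order],
            state_covs=small_truth.state_covs[order],
            transmat=small_truth.transmat[np.ix_(order, order)],
            initial=small_truth.initial[order],
        )
        perm = ss.align_states(permuted, small_truth)
        np.testing.assert_array_equal(perm, order)

    def test_unequal_k_rejected(self, small_truth):
        other = ss.make_truth(4, 5, separation=5, seed=2)
        with pytest.raises(ValueError, match="align"):
            ss.align_states(small_truth, other)
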