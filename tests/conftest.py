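import numpy as np
import pytest

import statesync as ss
from statesync.hmm_core import StatePathSet


@pytest.fixture(scope="session")
def small_truth():
    """Well-separated 3-state, 5-region ground truth."""
    return ss.make_truth(3, 5, separation=5.0, seed=1)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    """10-subject cohort (5 A / 5 B), 300 volumes, with true paths."""
    cohort, paths = ss.simulate_cohort(small_truth, (5, 5), T=300, seed=2)
    return cohort, paths


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    cohort, _ = small_cohort
    return ss.fit_hmm(cohort, 3, n_restarts=2, seed=3)


@pytest.fixture()
def toy_pathset():
    """Hand-written 2-subject, 4-state path set for dynamics arithmetic."""
    paths = np.array([
        [0, 0, 0, 1, 1, 2, 2, 2, 2, 0],
        [1, 1, 1, 1, 0, 0, 3, 3, 3, 3],
    ])
    return StatePathSet(paths, K=4, subject_ids=["s1", "s2"],
                        group_labels=["A", "B"])


def _enumerate_path_logprobs(init, trans, means, covs, series):
    """Joint log-probability of every one of the K^T state paths.

    Independent enumeration oracle: emissions through scipy's multivariate
    normal, transitions by table lookup over the exhaustive path list
    (lexicographic order).  Tiny instances only.
    """
    from itertools import product

    from scipy.stats import multivariate_normal

    T = series.shape[0]
    K = init.shape[0]
    log_b = np.stack([
        np.atleast_1d(multivariate_normal.logpdf(series, means[k], covs[k]))
        for k in range(K)
    ], axis=1)                                            # (T, K)
    paths = np.array(list(product(range(K), repeat=T)))   # (K^T, T), lex order
    with np.errstate(divide="ignore"):
        lp = np.log(init)[paths[:, 0]] + log_b[0, paths[:, 0]]
        for t in range(1, T):
            lp = lp + np.log(trans)[paths[:, t - 1], paths[:, t]] + log_b[t, paths[:, t]]
    return paths, lp


def brute_force_loglik(init, trans, means, covs, series):
    """Path-enumeration oracle for the HMM likelihood (tiny instances only)."""
    _, lp = _enumerate_path_logprobs(init, trans, means, covs, series)
    return float(np.logaddexp.reduce(lp))


def brute_force_viterbi(init, trans, means, covs, series):
    """Exhaustive argmax over all state paths; lexicographically first winner."""
    paths, lp = _enumerate_path_logprobs(init, trans, means, covs, series)
    best = int(np.argmax(lp))  # first occurrence = lexicographically smallest
    return paths[best], float(lp[best])


def random_toy_hmm(rng, K, R=1):
    """Random valid HMM parameters for oracle comparisons."""
    init = rng.dirichlet(np.ones(K))
    trans = rng.dirichlet(np.ones(K), size=K)
    means = rng.normal(0, 2, size=(K, R))
    covs = np.stack([np.eye(R) * rng.uniform(0.5, 2.0) for _ in range(K)])
    return init, trans, means, covs
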