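"""Gaussian-observation hidden Markov model on concatenated cohort series.

The cohort's subject series share one set of HMM parameters (the group-level
model), but the forward-backward recursions and Viterbi decoding restart at
every subject boundary with the shared initial distribution — concatenation
must never create spurious transitions between the last volume of one
subject and the first of the next.

Fitting is expectation-maximisation (Baum-Welch) in the log domain, with
k-means-initialised restarts; model order is selected by the Akaike
Information Criterion.  Because all subjects share the volume count, the
forward-backward pass is vectorised across subjects (one small matrix
product per time step) which keeps cohort-scale fits fast on a single CPU.

Numerical choices
-----------------
* All recursions in log space with max-shifted sum-exp reductions.
* Covariance updates get a ridge of ``1e-6 x mean variance`` on the
  diagonal; if an update still fails a Cholesky factorisation the ridge is
  escalated tenfold a few times before a degenerate-fit error is raised.
* Viterbi ties are broken toward the lexicographically smallest state path
  (lowest state index, scanning forward).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .dataio import CohortSeries

__all__ = [
    "HmmFit",
    "StatePathSet",
    "DegenerateFitError",
    "fit_hmm",
    "log_likelihood",
    "aic",
    "select_k",
    "viterbi",
    "decode_paths",
    "align_states",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class DegenerateFitError(RuntimeError):
    """Raised when a covariance update cannot be kept positive-definite."""


@dataclasses.dataclass
class HmmFit:
    """A fitted K-state Gaussian HMM plus fit metadata."""

    K: int
    means: np.ndarray            # (K, R)
    covs: np.ndarray             # (K, R, R)
    transmat: np.ndarray         # (K, K) row-stochastic
    initial: np.ndarray          # (K,)
    loglik_trace: np.ndarray     # per-EM-iteration total log-likelihood
    covariance_type: str = "full"
    converged: bool = False
    seed: int | None = None
    restart: int | None = None
    warnings: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.means.shape[1]

    @property
    def n_params(self) -> int:
        """Free parameters: initial (K-1) + transitions K(K-1) + means KR + covariances."""
        K, R = self.K, self.n_regions
        cov_dof = R * (R + 1) // 2 if self.covariance_type == "full" else R
        return (K - 1) + K * (K - 1) + K * R + K * cov_dof

    @property
    def final_loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "K": self.K,
            "covariance_type": self.covariance_type,
            "means": self.means.tolist(),
            "covs": self.covs.tolist(),
            "transmat": self.transmat.tolist(),
            "initial": self.initial.tolist(),
            "loglik_trace": np.asarray(self.loglik_trace).tolist(),
            "converged": bool(self.converged),
            "seed": self.seed,
            "restart": self.restart,
            "warnings": list(self.warnings),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "HmmFit":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            K=d["K"],
            means=np.asarray(d["means"], dtype=float),
            covs=np.asarray(d["covs"], dtype=float),
            transmat=np.asarray(d["transmat"], dtype=float),
            initial=np.asarray(d["initial"], dtype=float),
            loglik_trace=np.asarray(d["loglik_trace"], dtype=float),
            covariance_type=d.get("covariance_type", "full"),
            converged=d.get("converged", False),
            seed=d.get("seed"),
            restart=d.get("restart"),
            warnings=list(d.get("warnings", [])),
        )


@dataclasses.dataclass
class StatePathSet:
    """Per-subject decoded (or simulated) integer state sequences."""

    paths: np.ndarray            # (n_subjects, T) ints in [0, K)
    K: int
    subject_ids: list[str] | None = None
    group_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.paths = np.asarray(self.paths, dtype=np.int64)
        if self.paths.ndim != 2:
            raise ValueError("paths must be (subjects, volumes)")
        if self.paths.size and (self.paths.min() < 0 or self.paths.max() >= self.K):
            raise ValueError("state indices outside [0, K)")

    @property
    def n_subjects(self) -> int:
        return self.paths.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.paths.shape[1]

    def subset(self, idx: np.ndarray) -> "StatePathSet":
        idx = np.asarray(idx)
        return StatePathSet(
            paths=self.paths[idx],
            K=self.K,
            subject_ids=[self.subject_ids[i] for i in idx] if self.subject_ids else None,
            group_labels=[self.group_labels[i] for i in idx] if self.group_labels else None,
        )

    def group_indices(self, group: str) -> np.ndarray:
        if self.group_labels is None:
            raise ValueError("no group labels attached")
        return np.flatnonzero(np.asarray(self.group_labels) == group)


# ---------------------------------------------------------------------------
# emission log-densities
# ---------------------------------------------------------------------------

def _emission_logprob(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Log N(x | mu_k, Sigma_k) for every frame and state.

    X : (N, R) flattened frames;  returns (N, K).
    """
    N, R = X.shape
    K = means.shape[0]
    out = np.empty((N, K))
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        diff = X - means[k]
        z = solve_triangular(L, diff.T, lower=True, check_finite=False)
        quad = np.einsum("rn,rn->n", z, z)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, k] = -0.5 * (R * _LOG_2PI + logdet + quad)
    return out


def _logsumexp_last(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=-1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    return (m + np.log(np.exp(a - m).sum(axis=-1, keepdims=True)))[..., 0]


def _forward_backward(
    log_b: np.ndarray, log_init: np.ndarray, log_trans: np.ndarray
):
    """Batched log-domain forward-backward over independent sequences.

    log_b : (n, T, K) emission log-probabilities, one sequence per subject.
    Returns (log_alpha, log_beta, ll) with ll the per-sequence log-likelihood.
    """
    n, T, K = log_b.shape
    A = np.exp(log_trans)
    log_alpha = np.empty_like(log_b)
    log_alpha[:, 0] = log_init + log_b[:, 0]
    with np.errstate(divide="ignore"):
        for t in range(1, T):
            la = log_alpha[:, t - 1]
            m = la.max(axis=1, keepdims=True)
            log_alpha[:, t] = log_b[:, t] + m + np.log(np.exp(la - m) @ A)
        log_beta = np.empty_like(log_b)
        log_beta[:, T - 1] = 0.0
        for t in range(T - 2, -1, -1):
            v = log_b[:, t + 1] + log_beta[:, t + 1]
            m = v.max(axis=1, keepdims=True)
            log_beta[:, t] = m + np.log(np.exp(v - m) @ A.T)
    ll = _logsumexp_last(log_alpha[:, -1])
    return log_alpha, log_beta, ll


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _regularise(cov: np.ndarray, strength: float = 1e-6) -> np.ndarray:
    """Ridge the diagonal until the matrix factorises; raise if hopeless."""
    base = max(np.trace(cov) / cov.shape[0], 1e-12)
    ridge = strength * base
    for _ in range(8):
        try:
            np.linalg.cholesky(cov + ridge * np.eye(cov.shape[0]))
            return cov + ridge * np.eye(cov.shape[0])
        except np.linalg.LinAlgError:
            ridge *= 10.0
    raise DegenerateFitError("covariance update lost positive-definiteness")


def _kmeans_init(X: np.ndarray, n_subj: int, T: int, K: int, rs: int, cov_type: str):
    """Initial parameters from a k-means partition of the pooled frames."""
    max_frames = 20000
    if X.shape[0] > max_frames:
        sub_idx = np.random.default_rng(rs).choice(X.shape[0], max_frames, replace=False)
        km = KMeans(n_clusters=K, n_init=1, random_state=rs).fit(X[sub_idx])
    else:
        km = KMeans(n_clusters=K, n_init=1, random_state=rs).fit(X)
    means = km.cluster_centers_.copy()
    labels = km.predict(X).reshape(n_subj, T)
    R = X.shape[1]
    gcov = np.cov(X.T).reshape(R, R)
    covs = np.empty((K, R, R))
    for k in range(K):
        sel = (labels.ravel() == k)
        if sel.sum() > R + 1:
            c = np.cov(X[sel].T).reshape(R, R)
        else:
            c = gcov
        covs[k] = _regularise(c if cov_type == "full" else np.diag(np.diag(c)), 1e-4)
    counts = np.ones((K, K))
    src, dst = labels[:, :-1].ravel(), labels[:, 1:].ravel()
    np.add.at(counts, (src, dst), 1.0)
    transmat = counts / counts.sum(axis=1, keepdims=True)
    initial = np.bincount(labels[:, 0], minlength=K).astype(float) + 1.0
    initial /= initial.sum()
    return means, covs, transmat, initial


def _em_run(
    data: np.ndarray,
    K: int,
    max_iter: int,
    tol: float,
    rs: int,
    cov_type: str,
):
    n_subj, T, R = data.shape
    X = data.reshape(-1, R)
    means, covs, transmat, initial = _kmeans_init(X, n_subj, T, K, rs, cov_type)
    trace = []
    converged = False
    floor = 1e-300
    for _ in range(max_iter):
        log_b = _emission_logprob(X, means, covs).reshape(n_subj, T, K)
        with np.errstate(divide="ignore"):
            log_init = np.log(np.maximum(initial, floor))
            log_trans = np.log(np.maximum(transmat, floor))
        log_alpha, log_beta, ll_per = _forward_backward(log_b, log_init, log_trans)
        total_ll = float(ll_per.sum())
        trace.append(total_ll)
        if len(trace) > 1 and (total_ll - trace[-2]) < tol * max(1.0, abs(total_ll)):
            converged = True
            break

        log_gamma = log_alpha + log_beta - ll_per[:, None, None]
        gamma = np.exp(log_gamma)                     # (n, T, K)
        # transition expected counts, accumulated over t and subjects
        xi_sum = np.zeros((K, K))
        for t in range(T - 1):
            contrib = np.exp(
                log_alpha[:, t, :, None]
                + log_trans[None, :, :]
                + (log_b[:, t + 1] + log_beta[:, t + 1])[:, None, :]
                - ll_per[:, None, None]
            )
            xi_sum += contrib.sum(axis=0)

        initial = gamma[:, 0, :].sum(axis=0)
        initial = np.maximum(initial, floor)
        initial /= initial.sum()
        rowsum = xi_sum.sum(axis=1, keepdims=True)
        transmat = np.where(rowsum > 0, xi_sum / np.maximum(rowsum, floor), 1.0 / K)
        transmat /= transmat.sum(axis=1, keepdims=True)

        g_flat = gamma.reshape(-1, K)
        weights = g_flat.sum(axis=0)                  # (K,)
        means = (g_flat.T @ X) / np.maximum(weights[:, None], floor)
        for k in range(K):
            diff = X - means[k]
            wk = g_flat[:, k]
            cov = (diff * wk[:, None]).T @ diff / max(weights[k], floor)
            if cov_type == "diag":
                cov = np.diag(np.diag(cov))
            covs[k] = _regularise(cov)
    return means, covs, transmat, initial, np.asarray(trace), converged


def fit_hmm(
    cohort: CohortSeries,
    K: int,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_restarts: int = 5,
    seed: int = 0,
    covariance_type: str = "full",
) -> HmmFit:
    """Fit a K-state Gaussian HMM to the concatenated cohort by EM.

    All subjects contribute to one shared parameter set; recursions reset at
    subject boundaries.  ``n_restarts`` seeded k-means-initialised runs are
    performed and the one with the highest final log-likelihood is kept
    (ties broken by restart order).  ``tol`` is a relative log-likelihood
    improvement threshold.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if covariance_type not in {"full", "diag"}:
        raise ValueError("covariance_type must be 'full' or 'diag'")
    n_obs = cohort.n_subjects * cohort.n_volumes
    warnings: list[str] = []
    if n_obs < 10 * K * cohort.n_regions:
        warnings.append(
            f"only {n_obs} frames for K={K}, R={cohort.n_regions}: fit may be unstable"
        )
    restart_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_restarts)
    best = None
    for r, rs in enumerate(restart_seeds):
        means, covs, transmat, initial, trace, conv = _em_run(
            cohort.data, K, max_iter, tol, int(rs), covariance_type
        )
        if best is None or trace[-1] > best.final_loglik:
            best = HmmFit(
                K=K, means=means, covs=covs, transmat=transmat, initial=initial,
                loglik_trace=trace, covariance_type=covariance_type,
                converged=conv, seed=seed, restart=r, warnings=warnings,
            )
    assert best is not None
    return best


def log_likelihood(fit: HmmFit, series: np.ndarray) -> float:
    """Exact forward-algorithm log-likelihood of one subject's (T, R) series."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[1] != fit.n_regions:
        raise ValueError(
            f"series has {series.shape[1]} regions, model expects {fit.n_regions}"
        )
    log_b = _emission_logprob(series, fit.means, fit.covs)[None]
    with np.errstate(divide="ignore"):
        _, _, ll = _forward_backward(
            log_b, np.log(np.maximum(fit.initial, 1e-300)),
            np.log(np.maximum(fit.transmat, 1e-300)),
        )
    return float(ll[0])


def total_log_likelihood(fit: HmmFit, cohort: CohortSeries) -> float:
    """Sum of per-subject forward log-likelihoods (boundary-reset convention)."""
    log_b = _emission_logprob(
        cohort.data.reshape(-1, cohort.n_regions), fit.means, fit.covs
    ).reshape(cohort.n_subjects, cohort.n_volumes, fit.K)
    with np.errstate(divide="ignore"):
        _, _, ll = _forward_backward(
            log_b, np.log(np.maximum(fit.initial, 1e-300)),
            np.log(np.maximum(fit.transmat, 1e-300)),
        )
    return float(ll.sum())


def aic(fit: HmmFit, cohort: CohortSeries) -> float:
    """Akaike Information Criterion: ``2 * n_params - 2 * total log-likelihood``."""
    return 2.0 * fit.n_params - 2.0 * total_log_likelihood(fit, cohort)


def select_k(
    cohort: CohortSeries,
    k_range: Sequence[int],
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, "np.ndarray"]:
    """Fit every K in ``k_range`` and return (argmin-AIC K, AIC table).

    The AIC table is a structured array with fields ``K`` and ``aic`` in the
    order of ``k_range``.
    """
    if not len(k_range):
        raise ValueError("k_range must be non-empty")
    rows = []
    for K in k_range:
        try:
            fit = fit_hmm(cohort, K, seed=seed, **fit_kwargs)
        except Exception as exc:  # annotate which K failed
            raise RuntimeError(f"fit failed for K={K}: {exc}") from exc
        rows.append((K, aic(fit, cohort)))
    table = np.array(rows, dtype=[("K", int), ("aic", float)])
    best_k = int(table["K"][np.argmin(table["aic"])])
    return best_k, table


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def viterbi(fit: HmmFit, series: np.ndarray) -> np.ndarray:
    """Most probable state path for one subject (log-domain DP).

    Among equally likely paths the lexicographically smallest (lowest state
    index, scanning from the first volume) is returned: the DP computes, for
    each (t, state), the best score of any completion from t onward, then
    walks forward taking the lowest-index argmax at every step.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[1] != fit.n_regions:
        raise ValueError("region count mismatch")
    T = series.shape[0]
    K = fit.K
    log_b = _emission_logprob(series, fit.means, fit.covs)
    with np.errstate(divide="ignore"):
        log_trans = np.log(np.maximum(fit.transmat, 1e-300))
        log_init = np.log(np.maximum(fit.initial, 1e-300))
    omega = np.empty((T, K))           # best completion score from t given state
    omega[T - 1] = log_b[T - 1]
    for t in range(T - 2, -1, -1):
        omega[t] = log_b[t] + (log_trans + omega[t + 1][None, :]).max(axis=1)
    path = np.empty(T, dtype=np.int64)
    path[0] = int(np.argmax(log_init + omega[0]))
    for t in range(1, T):
        path[t] = int(np.argmax(log_trans[path[t - 1]] + omega[t]))
    return path


def decode_paths(fit: HmmFit, cohort: CohortSeries) -> StatePathSet:
    """Viterbi-decode every subject of a cohort."""
    paths = np.stack([viterbi(fit, cohort.data[i]) for i in range(cohort.n_subjects)])
    return StatePathSet(
        paths=paths, K=fit.K,
        subject_ids=list(cohort.subject_ids),
        group_labels=list(cohort.group_labels),
    )


def align_states(
    fit_or_paths,
    reference,
    decoded_paths: np.ndarray | None = None,
    reference_paths: np.ndarray | None = None,
) -> np.ndarray:
    """Resolve label switching: permutation ``perm`` with ``perm[fitted] = reference``.

    If decoded and reference paths are given, the assignment maximises total
    path agreement (Hungarian algorithm on the confusion matrix); otherwise
    it minimises the Euclidean distance between state means.  ``fit_or_paths``
    and ``reference`` must expose ``.means``/``.state_means`` in the
    mean-distance case.
    """
    if decoded_paths is not None and reference_paths is not None:
        decoded_paths = np.asarray(decoded_paths).ravel()
        reference_paths = np.asarray(reference_paths).ravel()
        K = int(max(decoded_paths.max(), reference_paths.max())) + 1
        conf = np.zeros((K, K))
        np.add.at(conf, (decoded_paths, reference_paths), 1.0)
        row, col = linear_sum_assignment(-conf)
    else:
        m1 = getattr(fit_or_paths, "means", None)
        if m1 is None:
            m1 = fit_or_paths.state_means
        m2 = getattr(reference, "means", None)
        if m2 is None:
            m2 = reference.state_means
        if m1.shape != m2.shape:
            raise ValueError("state counts differ; cannot align")
        dist = np.linalg.norm(m1[:, None, :] - m2[None, :, :], axis=-1)
        row, col = linear_sum_assignment(dist)
    perm = np.empty_like(col)
    perm[row] = col
    return perm
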