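"""Synthetic cohorts with the statistical structure the pipeline assumes.

The study's participant data are not publicly deposited, so every downstream
stage is exercised on generated cohorts that emulate the study conditions:
two groups of 30 and 40 subjects, ~1400 retained volumes at TR 0.81 s,
25 regions, latent state sequences from a K-state Markov chain with
group-specific planted synchrony epochs, Gaussian state-conditional
emissions, and facial action-unit series with event-locked positive-affect
responses whose amplitude is blunted in one group.

Planting acts on the *latent path*, not on the emissions, so the HMM-fitting
stage genuinely has to recover the planted structure from signal.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import ANALYSIS_AUS, DEFAULT_TR, CohortSeries

__all__ = [
    "TruthModel",
    "PlantedSync",
    "make_truth",
    "simulate_cohort",
    "simulate_au_cohort",
    "simulate_epoch_behaviour",
    "SMILE_AUS",
]

#: AUs carrying the positive-affect (smile) response; the group amplitude
#: difference is planted on exactly these six.
SMILE_AUS = ("AU06", "AU07", "AU09", "AU12", "AU14", "AU25")


@dataclasses.dataclass
class TruthModel:
    """Ground-truth Gaussian-emission HMM used to generate cohorts."""

    n_states: int
    state_means: np.ndarray      # (K, R)
    state_covs: np.ndarray       # (K, R, R) symmetric positive-definite
    transmat: np.ndarray         # (K, K) row-stochastic
    initial: np.ndarray          # (K,) simplex
    seed: int

    def __post_init__(self) -> None:
        K = self.n_states
        assert self.state_means.shape[0] == K
        assert np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(self.initial.sum(), 1.0, atol=1e-12)
        for c in self.state_covs:
            np.linalg.cholesky(c)  # raises if not PD

    @property
    def n_regions(self) -> int:
        return self.state_means.shape[1]


@dataclasses.dataclass
class PlantedSync:
    """A synchrony epoch forced onto one group's latent paths.

    During each window, every subject of ``group`` is forced into ``state``
    at each volume independently with probability ``adherence``.
    """

    group: str                       # "A" | "B"
    state: int
    windows: Sequence[tuple[int, int]]   # half-open volume intervals
    adherence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.adherence <= 1.0:
            raise ValueError("adherence must be in [0, 1]")
        if self.group not in {"A", "B"}:
            raise ValueError("group must be 'A' or 'B'")


def make_truth(
    K: int,
    R: int,
    separation: float = 5.0,
    seed: int = 0,
    stay_prob: float = 0.85,
    cov_scale: float = 1.0,
    full_cov: bool = False,
) -> TruthModel:
    """Draw a ground-truth model with pairwise mean separation >= ``separation``.

    Means are sampled i.i.d. Gaussian with scale ``max(separation, 1)`` and
    redrawn until every pair is at least ``separation`` apart in Euclidean
    norm.  The transition matrix is sticky (diagonal ~= ``stay_prob``, the
    empirical regime of fMRI state sequences) with Dirichlet off-diagonal
    mass.  Covariances are spherical ``cov_scale * I`` by default; with
    ``full_cov`` a random well-conditioned SPD matrix per state.
    """
    if K < 2 or R < 1:
        raise ValueError("need K >= 2 states and R >= 1 regions")
    rng = np.random.default_rng(seed)
    scale = max(separation, 1.0)
    means = None
    for _ in range(500):
        cand = rng.normal(0.0, scale, size=(K, R))
        d = np.linalg.norm(cand[:, None, :] - cand[None, :, :], axis=-1)
        if d[np.triu_indices(K, 1)].min() >= separation:
            means = cand
            break
    if means is None:
        raise ValueError(
            f"could not place {K} means at separation {separation} in {R} "
            f"dimensions; reduce separation or K, or increase R"
        )
    if full_cov:
        covs = np.empty((K, R, R))
        for k in range(K):
            A = rng.normal(size=(R, R)) / np.sqrt(R)
            covs[k] = cov_scale * (A @ A.T + np.eye(R))
    else:
        covs = np.broadcast_to(cov_scale * np.eye(R), (K, R, R)).copy()
    off = rng.dirichlet(np.ones(K - 1), size=K) * (1.0 - stay_prob)
    transmat = np.full((K, K), 0.0)
    for k in range(K):
        transmat[k] = np.insert(off[k], k, stay_prob)
    transmat /= transmat.sum(axis=1, keepdims=True)
    initial = rng.dirichlet(np.ones(K))
    return TruthModel(
        n_states=K, state_means=means, state_covs=np.asarray(covs),
        transmat=transmat, initial=initial, seed=seed,
    )


def _simulate_paths(
    truth: TruthModel,
    n_subjects: int,
    T: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent Markov-chain paths, vectorised over subjects."""
    K = truth.n_states
    cum_init = np.cumsum(truth.initial)
    cum_trans = np.cumsum(truth.transmat, axis=1)
    paths = np.empty((n_subjects, T), dtype=np.int64)
    u = rng.random(n_subjects)
    paths[:, 0] = np.searchsorted(cum_init, u, side="right").clip(max=K - 1)
    U = rng.random((n_subjects, T - 1))
    for t in range(1, T):
        rows = cum_trans[paths[:, t - 1]]
        paths[:, t] = (U[:, t - 1][:, None] >= rows).sum(axis=1).clip(max=K - 1)
    return paths


def simulate_cohort(
    truth: TruthModel,
    n_per_group: tuple[int, int] = (30, 40),
    T: int = 1400,
    planted: Sequence[PlantedSync] = (),
    seed: int = 0,
    tr_seconds: float = DEFAULT_TR,
):
    """Simulate a two-group cohort; returns ``(CohortSeries, true_paths)``.

    ``true_paths`` is an ``(n_subjects, T)`` integer array of the latent
    states actually emitted, for recovery tests.  Planted windows overwrite
    the Markov path (each volume independently with probability
    ``adherence``) before emissions are drawn, so emissions always reflect
    the final path.
    """
    n_a, n_b = n_per_group
    if n_a <= 0 or n_b <= 0:
        raise ValueError("both groups must be non-empty")
    for p in planted:
        for start, stop in p.windows:
            if not (0 <= start < stop <= T):
                raise ValueError(f"planted window [{start}, {stop}) outside [0, {T})")
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    groups = np.array(["A"] * n_a + ["B"] * n_b)
    paths = _simulate_paths(truth, n, T, rng)

    for p in planted:
        members = np.flatnonzero(groups == p.group)
        for start, stop in p.windows:
            width = stop - start
            force = rng.random((members.size, width)) < p.adherence
            block = paths[np.ix_(members, range(start, stop))]
            block[force] = p.state
            paths[np.ix_(members, range(start, stop))] = block

    R = truth.n_regions
    chols = np.linalg.cholesky(truth.state_covs)
    noise = rng.standard_normal((n, T, R))
    # Correlated noise per state: x = mu_k + L_k @ z.  Vectorise by state to
    # avoid materialising a (n, T, R, R) tensor.
    data = truth.state_means[paths].copy()
    for k in range(truth.n_states):
        sel = paths == k
        data[sel] += noise[sel] @ chols[k].T
    cohort = CohortSeries(
        data=data,
        tr_seconds=tr_seconds,
        subject_ids=[f"sub-{i+1:03d}" for i in range(n)],
        region_ids=[f"roi-{j+1:02d}" for j in range(R)],
        group_labels=[str(g) for g in groups],
    )
    return cohort, paths


def _gamma_kernel(fps: float, peak_s: float = 1.5, width: int | None = None) -> np.ndarray:
    """Gamma-shaped response kernel (unit peak) for event-locked AU bumps."""
    if width is None:
        width = int(round(6 * peak_s * fps))
    t = np.arange(width) / fps
    shape = 3.0
    k = t ** (shape - 1) * np.exp(-t * shape / peak_s)
    return k / k.max()


def simulate_au_cohort(
    n_per_group: tuple[int, int] = (30, 40),
    n_frames: int = 12000,
    event_times: Sequence[int] = (),
    amp: tuple[float, float] = (0.4, 1.0),
    ar1: float = 0.3,
    noise_sd: float = 0.3,
    fps: float = 10.0,
    seed: int = 0,
):
    """Simulate per-frame AU intensity series for a two-group cohort.

    Each AU series is baseline AR(1) noise plus gamma-shaped bumps locked to
    ``event_times`` (frame indices).  The six smile AUs (06, 07, 09, 12, 14,
    25) receive group-specific amplitudes ``amp = (amp_A, amp_B)`` —
    ``amp_A < amp_B`` emulates melancholic blunting of positive facial
    affect; all other AUs share a common amplitude.

    Returns ``(data, group_labels, au_ids)`` where ``data`` has shape
    ``(n_subjects, n_frames, 16)``.
    """
    if min(amp) < 0:
        raise ValueError("amplitudes must be non-negative")
    if not 0.0 <= ar1 < 1.0:
        raise ValueError("ar1 must lie in [0, 1) for stationarity")
    if event_times and max(event_times) >= n_frames:
        raise ValueError("event time beyond series length")
    n_a, n_b = n_per_group
    n = n_a + n_b
    rng = np.random.default_rng(seed)
    groups = np.array(["A"] * n_a + ["B"] * n_b)
    n_aus = len(ANALYSIS_AUS)
    smile_idx = np.array([ANALYSIS_AUS.index(a) for a in SMILE_AUS])

    # stationary AR(1) baseline
    innov_sd = noise_sd * np.sqrt(1.0 - ar1 ** 2)
    eps = rng.normal(0.0, innov_sd, size=(n, n_frames, n_aus))
    base = np.empty_like(eps)
    base[:, 0] = rng.normal(0.0, noise_sd, size=(n, n_aus))
    for t in range(1, n_frames):
        base[:, t] = ar1 * base[:, t - 1] + eps[:, t]

    bump = np.zeros(n_frames)
    kern = _gamma_kernel(fps)
    for et in event_times:
        stop = min(n_frames, et + kern.size)
        bump[et:stop] += kern[: stop - et]

    other_amp = amp[1]  # non-smile AUs share the unblunted amplitude
    amps = np.full((n, n_aus), other_amp)
    amps[np.ix_(groups == "A", smile_idx)] = amp[0]
    amps[np.ix_(groups == "B", smile_idx)] = amp[1]
    data = base + amps[:, None, :] * bump[None, :, None]
    data = np.clip(data + 1.0, 0.0, None)  # shift to the non-negative intensity scale
    return data, list(groups), list(ANALYSIS_AUS)


def simulate_epoch_behaviour(
    n_per_group: tuple[int, int] = (30, 39),
    slopes: tuple[float, float] = (-0.1, -1.0),
    intercepts: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired (facial_mean, roi_beta, group) table with group-specific slopes.

    Emulates a blunted brain-behaviour coupling in group A: ``roi_beta`` is
    linear in ``facial_mean`` with a group-specific slope plus Gaussian
    noise; the facial means are drawn from a common distribution so groups
    differ only in the coupling.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n_a, n_b = n_per_group
    rng = np.random.default_rng(seed)
    groups = np.array(["A"] * n_a + ["B"] * n_b)
    facial = rng.normal(1.0, 0.5, size=n_a + n_b)
    slope = np.where(groups == "A", slopes[0], slopes[1])
    icpt = np.where(groups == "A", intercepts[0], intercepts[1])
    beta = icpt + slope * facial + rng.normal(0.0, noise_sd, size=n_a + n_b)
    return pd.DataFrame({"facial_mean": facial, "roi_beta": beta, "group": groups})
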