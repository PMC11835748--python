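"""Windowed inter-subject brain-state consistency and its two null models.

The consistency score asks, for every state k and volume v: what percentage
of a group's subjects expressed state k at least once in the sliding window
of volumes [v - w, v + w] (default w = 3 TRs, a 7-TR window)?  Scores range
from 0% (no subject) to 100% (every subject); windows are truncated at the
series edges.

Two complementary nulls threshold the observed curves at their 95th
percentile:

* **Between-group null** — subjects are repeatedly re-split at random into
  pseudo-groups of the original group sizes; the resulting consistency
  surfaces capture how much synchrony arises from cohort-level structure
  regardless of the clinical grouping.  Per state x volume surface, one per
  group size.
* **Within-group null** — surrogate state paths are simulated from the
  group's empirical transition matrix (random initial state), destroying
  cross-subject temporal alignment while preserving marginal dynamics; the
  windowed consistency of each surrogate set is averaged over volumes,
  giving a scalar threshold per state.

A volume is flagged only when the observed consistency exceeds *both*
thresholds, and only inside the positive-scene mask; contiguous flagged runs
become synchrony events.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d

from .dataio import EpochMask
from .hmm_core import StatePathSet

__all__ = [
    "ConsistencyCurve",
    "NullThresholds",
    "SyncEvent",
    "presence_tensor",
    "windowed_consistency",
    "between_group_null",
    "within_group_null",
    "empirical_transmat",
    "flag_sync_events",
]


@dataclasses.dataclass
class ConsistencyCurve:
    """State x volume consistency percentages for one (pseudo-)group."""

    values: np.ndarray           # (K, T) in [0, 100]
    window: int                  # half-width w in volumes
    group: str | None = None
    n_members: int = 0


@dataclasses.dataclass
class NullThresholds:
    """95th-percentile thresholds from the two null models for one group."""

    between: np.ndarray          # (K, T) surface
    within: np.ndarray           # (K,) scalars
    n_iterations: int
    seed: int | None = None


@dataclasses.dataclass
class SyncEvent:
    group: str | None
    state: int
    start: int                   # volume index, half-open interval
    end: int
    peak: float                  # max consistency inside the event


def presence_tensor(paths: np.ndarray, K: int, w: int) -> np.ndarray:
    """Boolean (n_subjects, K, T): state k present in window [v-w, v+w].

    Edge windows are truncated (constant-False padding outside the series).
    """
    paths = np.asarray(paths)
    n, T = paths.shape
    out = np.empty((n, K, T), dtype=bool)
    size = 2 * w + 1
    for k in range(K):
        ind = (paths == k)
        if w == 0:
            out[:, k] = ind
        else:
            out[:, k] = maximum_filter1d(
                ind.astype(np.uint8), size=size, axis=1, mode="constant", cval=0
            ).astype(bool)
    return out


def windowed_consistency(
    paths: StatePathSet,
    members: Sequence[int] | None = None,
    w: int = 3,
    group: str | None = None,
) -> ConsistencyCurve:
    """Percentage of ``members`` expressing each state near each volume.

    ``members`` are subject indices (default: all subjects; or pass a group
    tag via ``group`` when the path set carries labels).
    """
    if w < 0:
        raise ValueError("window half-width must be >= 0")
    if group is not None and members is None:
        members = paths.group_indices(group)
    if members is None:
        members = np.arange(paths.n_subjects)
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("empty member set")
    pres = presence_tensor(paths.paths[members], paths.K, w)
    values = 100.0 * pres.mean(axis=0)
    return ConsistencyCurve(values=values, window=w, group=group, n_members=members.size)


def between_group_null(
    paths: StatePathSet,
    sizes: tuple[int, int],
    n_iter: int = 1000,
    seed: int = 0,
    w: int = 3,
    percentile: float = 95.0,
) -> dict[int, np.ndarray]:
    """Pseudo-group consistency surfaces at the requested percentile.

    Each iteration splits the whole cohort, without replacement, into
    pseudo-groups of the two original sizes and computes both consistency
    curves.  Returns ``{size: (K, T) percentile surface}`` — look up the
    surface matching a group's size when thresholding that group's curve.
    """
    n_a, n_b = sizes
    if n_a + n_b != paths.n_subjects:
        raise ValueError(
            f"sizes {sizes} do not partition the cohort of {paths.n_subjects}"
        )
    pres = presence_tensor(paths.paths, paths.K, w).astype(np.float32)
    rng = np.random.default_rng(seed)
    K, T = paths.K, paths.n_volumes
    curves = {n_a: np.empty((n_iter, K, T), dtype=np.float32),
              n_b: np.empty((n_iter, K, T), dtype=np.float32)}
    for i in range(n_iter):
        perm = rng.permutation(paths.n_subjects)
        curves[n_a][i] = 100.0 * pres[perm[:n_a]].mean(axis=0)
        curves[n_b][i] = 100.0 * pres[perm[n_a:]].mean(axis=0)
    return {
        size: np.percentile(arr, percentile, axis=0).astype(float)
        for size, arr in curves.items()
    }


def empirical_transmat(paths: np.ndarray, K: int, mask=None) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-count transition matrix of a group's paths.

    Counts consecutive pairs across all subjects (restricted to contiguous
    masked segments when a mask is given).  Rows with no observed exits fall
    back to the self-transition convention and are flagged.

    Returns ``(transmat, defined_rows)``.
    """
    paths = np.asarray(paths)
    counts = np.zeros((K, K))
    if mask is not None:
        values = mask.values if isinstance(mask, EpochMask) else np.asarray(mask, bool)
        from .state_dynamics import _masked_segments
        segments = list(_masked_segments(values))
    else:
        segments = [(0, paths.shape[1])]
    for start, stop in segments:
        if stop - start < 2:
            continue
        seg = paths[:, start:stop]
        np.add.at(counts, (seg[:, :-1].ravel(), seg[:, 1:].ravel()), 1.0)
    rowsum = counts.sum(axis=1)
    defined = rowsum > 0
    transmat = np.where(
        defined[:, None], counts / np.maximum(rowsum[:, None], 1.0), np.eye(K)
    )
    return transmat, defined


def _simulate_chains(
    transmat: np.ndarray, n_chains: int, T: int, rng: np.random.Generator,
    initial: np.ndarray | None = None,
) -> np.ndarray:
    """(n_chains, T) surrogate Markov paths; uniform initial state by default."""
    K = transmat.shape[0]
    cum = np.cumsum(transmat, axis=1)
    out = np.empty((n_chains, T), dtype=np.int64)
    if initial is None:
        out[:, 0] = rng.integers(0, K, size=n_chains)
    else:
        out[:, 0] = np.searchsorted(np.cumsum(initial), rng.random(n_chains),
                                    side="right").clip(max=K - 1)
    U = rng.random((n_chains, T - 1))
    for t in range(1, T):
        rows = cum[out[:, t - 1]]
        out[:, t] = (U[:, t - 1][:, None] >= rows).sum(axis=1).clip(max=K - 1)
    return out


def within_group_null(
    group_paths: StatePathSet,
    n_iter: int = 1000,
    seed: int = 0,
    w: int = 3,
    percentile: float = 95.0,
    mask=None,
    transmat: np.ndarray | None = None,
    initial: str = "uniform",
    pooled: bool = False,
) -> np.ndarray:
    """Surrogate-path null thresholds, one scalar per state (or one pooled).

    Each iteration simulates one surrogate Markov path per group member from
    the group's empirical transition matrix (or a supplied ``transmat``,
    e.g. the joint HMM fit's), computes the windowed consistency of the
    surrogate set and averages it over volumes, giving one value per state
    per iteration; the requested percentile across iterations is returned.

    ``initial``: "uniform" draws the first state uniformly; "stationary"
    uses the chain's stationary distribution.
    """
    if group_paths.n_subjects < 2:
        raise ValueError("need >= 2 subjects in the group")
    K = group_paths.K
    T = group_paths.n_volumes
    if transmat is None:
        # degenerate rows already carry the flagged self-transition convention
        transmat, _ = empirical_transmat(group_paths.paths, K, mask=mask)
    init = None
    if initial == "stationary":
        vals, vecs = np.linalg.eig(transmat.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        init = np.abs(pi) / np.abs(pi).sum()
    elif initial != "uniform":
        raise ValueError("initial must be 'uniform' or 'stationary'")
    rng = np.random.default_rng(seed)
    m = group_paths.n_subjects
    chains = _simulate_chains(transmat, n_iter * m, T, rng, initial=init)
    chains = chains.reshape(n_iter, m, T)
    per_iter = np.empty((n_iter, K))
    size = 2 * w + 1
    for k in range(K):
        ind = (chains == k).astype(np.uint8)
        if w > 0:
            ind = maximum_filter1d(ind, size=size, axis=2, mode="constant", cval=0)
        per_iter[:, k] = 100.0 * ind.mean(axis=(1, 2))
    if pooled:
        thr = float(np.percentile(per_iter.ravel(), percentile))
        return np.full(K, thr)
    return np.percentile(per_iter, percentile, axis=0)


def flag_sync_events(
    curve: ConsistencyCurve,
    nulls: NullThresholds,
    mask,
    min_run: int = 1,
) -> list[SyncEvent]:
    """Volumes beating *both* nulls inside the mask, merged into events.

    A volume is flagged for state k when its consistency strictly exceeds
    both the between-group surface and the within-group scalar; contiguous
    flagged runs of at least ``min_run`` volumes become events, ranked by
    duration (longest first).
    """
    K, T = curve.values.shape
    mvals = mask.values if isinstance(mask, EpochMask) else np.asarray(mask, bool)
    if mvals.shape[0] != T or nulls.between.shape != (K, T) or nulls.within.shape[0] != K:
        raise ValueError("inconsistent shapes between curve, nulls and mask")
    flagged = (
        (curve.values > nulls.between)
        & (curve.values > nulls.within[:, None])
        & mvals[None, :]
    )
    events: list[SyncEvent] = []
    for k in range(K):
        padded = np.concatenate(([False], flagged[k], [False])).astype(int)
        d = np.diff(padded)
        for start, stop in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
            if stop - start >= min_run:
                events.append(SyncEvent(
                    group=curve.group, state=k, start=int(start), end=int(stop),
                    peak=float(curve.values[k, start:stop].max()),
                ))
    events.sort(key=lambda e: (-(e.end - e.start), e.state, e.start))
    return events
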