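"""State-dynamics summaries and group statistics over the positive-scene mask.

Per subject: fractional occupancy, dwell time and the transition-probability
matrix, all computed only from masked volumes, with runs and transitions
truncated at mask boundaries (a gap in the mask never contributes a visit
continuation or a transition pair).

Group inference: two-tailed unpaired t-tests with max-statistic permutation
family-wise error control for occupancy/dwell features, and a Network-Based
Statistic (NBS) style component test on the K x K transition probabilities —
edge-wise t-thresholding, weakly connected components of the supra-threshold
directed graph, component extent (edge count) against the permutation null of
the maximal component size.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dataio import EpochMask
from .hmm_core import StatePathSet

__all__ = [
    "DwellTable",
    "NbsComponent",
    "fractional_occupancy",
    "dwell_times",
    "transition_matrices",
    "group_compare_fwe",
    "nbs_transitions",
]


def _masked_segments(mask: np.ndarray):
    """Yield (start, stop) half-open runs of True in the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return
    padded = np.concatenate(([False], mask, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    yield from zip(starts, stops)


def _as_mask(mask, T: int) -> np.ndarray:
    values = mask.values if isinstance(mask, EpochMask) else np.asarray(mask, dtype=bool)
    if values.shape[0] != T:
        raise ValueError(f"mask length {values.shape[0]} != path length {T}")
    return values


def fractional_occupancy(paths: StatePathSet, mask) -> pd.DataFrame:
    """Fraction of masked volumes each subject spends in each state.

    Rows (subjects) sum to 1 exactly.
    """
    m = _as_mask(mask, paths.n_volumes)
    if not m.any():
        raise ValueError("empty mask: no volumes to summarise")
    sel = paths.paths[:, m]
    counts = np.stack([(sel == k).sum(axis=1) for k in range(paths.K)], axis=1)
    occ = counts / m.sum()
    idx = paths.subject_ids or list(range(paths.n_subjects))
    return pd.DataFrame(occ, index=idx, columns=[f"state_{k}" for k in range(paths.K)])


@dataclasses.dataclass
class DwellTable:
    """Mean visit durations (seconds; NaN where never visited) and visit counts."""

    durations: pd.DataFrame
    counts: pd.DataFrame


def dwell_times(paths: StatePathSet, mask, tr_seconds: float) -> DwellTable:
    """Mean uninterrupted visit duration per subject and state.

    Visits are maximal same-state runs inside contiguous masked segments;
    a run crossing a mask gap is truncated into separate visits.
    """
    m = _as_mask(mask, paths.n_volumes)
    K = paths.K
    n = paths.n_subjects
    total = np.zeros((n, K))
    count = np.zeros((n, K), dtype=int)
    for start, stop in _masked_segments(m):
        seg = paths.paths[:, start:stop]
        change = np.ones(seg.shape, dtype=bool)
        change[:, 1:] = seg[:, 1:] != seg[:, :-1]
        for i in range(n):
            run_starts = np.flatnonzero(change[i])
            run_stops = np.append(run_starts[1:], seg.shape[1])
            states = seg[i, run_starts]
            lengths = run_stops - run_starts
            np.add.at(total[i], states, lengths)
            np.add.at(count[i], states, 1)
    with np.errstate(invalid="ignore"):
        mean_len = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    idx = paths.subject_ids or list(range(n))
    cols = [f"state_{k}" for k in range(K)]
    return DwellTable(
        durations=pd.DataFrame(mean_len * tr_seconds, index=idx, columns=cols),
        counts=pd.DataFrame(count, index=idx, columns=cols),
    )


def transition_matrices(paths: StatePathSet, mask):
    """Per-subject row-stochastic transition matrices over masked volume pairs.

    Only consecutive volume pairs lying inside the same contiguous masked
    segment are counted.  A state row with no observed exits follows the
    absorbing-row convention (1 on the diagonal) and is flagged in the
    returned ``defined`` array.

    Returns ``(tmats, defined)`` with shapes (n, K, K) and (n, K).
    """
    m = _as_mask(mask, paths.n_volumes)
    K = paths.K
    n = paths.n_subjects
    counts = np.zeros((n, K, K))
    for start, stop in _masked_segments(m):
        if stop - start < 2:
            continue
        seg = paths.paths[:, start:stop]
        src = seg[:, :-1]
        dst = seg[:, 1:]
        subj = np.repeat(np.arange(n), src.shape[1])
        np.add.at(counts, (subj, src.ravel(), dst.ravel()), 1.0)
    rowsum = counts.sum(axis=2)
    defined = rowsum > 0
    tmats = np.where(
        defined[:, :, None],
        counts / np.maximum(rowsum[:, :, None], 1.0),
        np.eye(K)[None],
    )
    return tmats, defined


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def _pooled_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised pooled-variance two-sample t over the last axis=features.

    x, y : (n_x, F) and (n_y, F).  Features with zero pooled variance give NaN.
    """
    nx_, ny_ = x.shape[0], y.shape[0]
    mx, my = x.mean(axis=0), y.mean(axis=0)
    vx = x.var(axis=0, ddof=1)
    vy = y.var(axis=0, ddof=1)
    sp2 = ((nx_ - 1) * vx + (ny_ - 1) * vy) / (nx_ + ny_ - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(sp2 * (1.0 / nx_ + 1.0 / ny_))
    return np.where(sp2 > 0, t, np.nan)


def _label_array(labels) -> np.ndarray:
    lab = np.asarray(labels)
    groups = np.unique(lab)
    if groups.size != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    return lab


def group_compare_fwe(
    values,
    labels,
    n_perm: int = 5000,
    seed: int = 0,
    exact: bool = False,
) -> pd.DataFrame:
    """Two-tailed t per feature with max-|t| permutation FWE correction.

    Group labels are permuted (``n_perm`` random shuffles, or every distinct
    split when ``exact``); the null is the permutation distribution of the
    maximum |t| across features, so p_fwe controls the family-wise error over
    the feature set.  Features with zero pooled variance report NaN.
    """
    X = np.asarray(values, dtype=float)
    if isinstance(values, pd.DataFrame):
        feat_names = list(values.columns)
    else:
        feat_names = [f"f{j}" for j in range(X.shape[1])]
    lab = _label_array(labels)
    g0, g1 = np.unique(lab)
    idx0 = np.flatnonzero(lab == g0)
    idx1 = np.flatnonzero(lab == g1)
    if idx0.size < 2 or idx1.size < 2:
        raise ValueError("need >= 2 subjects per group")
    t_obs = _pooled_t(X[idx0], X[idx1])
    finite = np.isfinite(t_obs)

    n = X.shape[0]
    n0 = idx0.size
    if exact:
        splits = [np.array(c) for c in combinations(range(n), n0)]
    else:
        rng = np.random.default_rng(seed)
        splits = [rng.permutation(n)[:n0] for _ in range(n_perm)]
    max_null = np.empty(len(splits))
    all_idx = np.arange(n)
    for i, s in enumerate(splits):
        rest = np.setdiff1d(all_idx, s, assume_unique=True)
        t_perm = _pooled_t(X[s], X[rest])
        vals = np.abs(t_perm[finite])
        max_null[i] = vals.max() if vals.size else np.nan
    p_fwe = np.full(X.shape[1], np.nan)
    denom = len(splits) if exact else len(splits) + 1
    for j in np.flatnonzero(finite):
        hits = np.sum(max_null >= abs(t_obs[j]) - 1e-12)
        p_fwe[j] = (hits if exact else hits + 1) / denom
    return pd.DataFrame({"t": t_obs, "p_fwe": p_fwe}, index=feat_names)


@dataclasses.dataclass
class NbsComponent:
    """A supra-threshold connected component of transition-probability edges."""

    edges: list[tuple[int, int]]
    size: int
    p_fwe: float


def nbs_transitions(
    tmats: np.ndarray,
    labels,
    t_thresh: float,
    n_perm: int = 5000,
    seed: int = 0,
) -> list[NbsComponent]:
    """NBS-style component test on subject transition matrices.

    Each directed edge k->l carries the subjects' transition probabilities;
    edges with |t| above ``t_thresh`` form a directed graph whose weakly
    connected components are scored by edge count.  Significance is the
    fraction of label permutations whose *maximal* component is at least as
    large.  An empty component list is a legitimate outcome, not an error.
    """
    if t_thresh <= 0:
        raise ValueError("t_thresh must be positive")
    tmats = np.asarray(tmats, dtype=float)
    n, K, _ = tmats.shape
    lab = _label_array(labels)
    X = tmats.reshape(n, K * K)
    g0, g1 = np.unique(lab)
    idx0 = np.flatnonzero(lab == g0)
    idx1 = np.flatnonzero(lab == g1)

    def max_component(t_flat: np.ndarray):
        with np.errstate(invalid="ignore"):
            supra = np.abs(t_flat.reshape(K, K)) > t_thresh
        g = nx.DiGraph()
        srcs, dsts = np.nonzero(supra)
        g.add_edges_from(zip(srcs.tolist(), dsts.tolist()))
        comps = []
        for nodes in nx.weakly_connected_components(g):
            edges = [(u, v) for u, v in g.edges if u in nodes and v in nodes]
            comps.append(edges)
        return comps

    obs_comps = max_component(_pooled_t(X[idx0], X[idx1]))
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    all_idx = np.arange(n)
    for i in range(n_perm):
        s = rng.permutation(n)[: idx0.size]
        rest = np.setdiff1d(all_idx, s, assume_unique=True)
        comps = max_component(_pooled_t(X[s], X[rest]))
        null_max[i] = max((len(c) for c in comps), default=0)
    out = []
    for edges in obs_comps:
        p = (1 + np.sum(null_max >= len(edges))) / (n_perm + 1)
        out.append(NbsComponent(edges=sorted(edges), size=len(edges), p_fwe=float(p)))
    out.sort(key=lambda c: (-c.size, c.p_fwe))
    return out
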