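"""Facial action-unit statistics for the melancholia comparison.

Works on per-frame AU intensity matrices (subjects x frames x 16 AUs at
10 fps, the OpenFace ``-au_static`` convention: no per-subject
normalisation, so between-subject amplitude differences are preserved).
Frames where face tracking failed are missing (NaN) and are excluded from
means rather than imputed.

Statistics: per-AU two-sample t with Benjamini-Hochberg FDR over the 16-AU
family; the first principal component of the pooled frames; bootstrap
percentile bands for group-mean time courses; and a Pearson screen against a
clinical covariate.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import ANALYSIS_AUS
from .synthcohort import SMILE_AUS

__all__ = [
    "au_mean_intensity",
    "two_sample_t_from_summary",
    "compare_au_groups",
    "first_pc",
    "bootstrap_band",
    "correlate_with_covariate",
]


def _as_array(aus, au_ids=None):
    data = np.asarray(aus, dtype=float)
    if data.ndim != 3:
        raise ValueError("AU data must be (subjects, frames, AUs)")
    if au_ids is None:
        au_ids = list(ANALYSIS_AUS)
    if data.shape[2] != len(au_ids):
        raise ValueError("AU id list does not match data")
    return data, list(au_ids)


def au_mean_intensity(aus, au_ids=None, subject_ids=None) -> pd.DataFrame:
    """Per-subject mean AU intensity over valid (non-missing) frames.

    No per-subject normalisation is applied (the -au_static semantics);
    missing frames are excluded from the denominator.  A subject with no
    valid frame for some AU is an error — there is nothing to average.
    """
    data, au_ids = _as_array(aus, au_ids)
    valid = np.isfinite(data)
    if not valid.any(axis=1).all():
        s, a = map(int, np.argwhere(~valid.any(axis=1))[0])
        raise ValueError(f"subject {s}: all frames missing for AU {au_ids[a]}")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(data, axis=1)
    idx = subject_ids if subject_ids is not None else list(range(data.shape[0]))
    return pd.DataFrame(means, index=idx, columns=au_ids)


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from group summaries.

    Returns ``(t, df, p)`` for the contrast ``mean1 - mean2`` with
    ``df = n1 + n2 - 2``.  Useful for re-deriving printed cohort-table t
    values from their printed means and SDs.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def compare_au_groups(
    means: pd.DataFrame,
    labels,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-tailed two-sample t per AU with BH-FDR across the AU family.

    The t statistic is signed as group B minus group A (non-melancholic
    minus melancholic in the study's labelling), so blunted expressivity in
    group A yields positive t on the affected AUs while higher symptom
    scores in group A yield negative t — matching the reporting convention
    of the study cohort table.  Pooled-variance t by default, Welch with
    ``equal_var=False``.
    """
    lab = np.asarray(labels)
    a = means.loc[lab == "A"]
    b = means.loc[lab == "B"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 subjects per group")
    rows = []
    for au in means.columns:
        x, y = b[au].to_numpy(), a[au].to_numpy()
        if np.var(np.concatenate([x, y]), ddof=1) == 0:
            rows.append((a[au].mean(), b[au].mean(), np.nan, np.nan))
            continue
        t, p = stats.ttest_ind(x, y, equal_var=equal_var)
        rows.append((a[au].mean(), b[au].mean(), float(t), float(p)))
    out = pd.DataFrame(
        rows, index=means.columns, columns=["mean_A", "mean_B", "t", "p"]
    )
    finite = out["p"].notna()
    q = np.full(len(out), np.nan)
    if finite.any():
        q[finite.to_numpy()] = multipletests(
            out.loc[finite, "p"].to_numpy(), method="fdr_bh"
        )[1]
    out["q"] = q
    return out


@dataclasses.dataclass
class FirstPcResult:
    loadings: pd.Series                  # per AU
    scores: np.ndarray                   # (n_subjects, n_frames), NaN at missing frames
    subject_means: np.ndarray            # (n_subjects,)
    explained_variance_ratio: float


def first_pc(aus, au_ids=None) -> FirstPcResult:
    """First principal component of the pooled frames x AU matrix.

    Frames from all subjects are pooled (group-blind) and centred per AU;
    the principal axis sign is fixed so that the mean loading over the six
    smile AUs is positive.  Per-subject score series are the projections of
    that subject's (centred) frames; frames with any missing AU get NaN
    scores and subject means ignore them.
    """
    data, au_ids = _as_array(aus, au_ids)
    n, T, A = data.shape
    pooled = data.reshape(-1, A)
    complete = np.isfinite(pooled).all(axis=1)
    if complete.sum() <= A:
        raise ValueError("need more complete pooled frames than AUs")
    centre = pooled[complete].mean(axis=0)
    Xc = pooled[complete] - centre
    # principal axis via SVD of the centred pool
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if (s[0] - s[1:]).min(initial=np.inf) < 1e-12 * max(s[0], 1.0):
        warnings.warn("leading principal axis is nearly degenerate", RuntimeWarning)
    axis = vt[0]
    smile_idx = [au_ids.index(a) for a in SMILE_AUS if a in au_ids]
    if smile_idx and axis[smile_idx].mean() < 0:
        axis = -axis
    evr = float(s[0] ** 2 / (s**2).sum())
    scores = np.full((n * T,), np.nan)
    scores[complete] = Xc @ axis
    scores = scores.reshape(n, T)
    with np.errstate(invalid="ignore"):
        subject_means = np.nanmean(scores, axis=1)
    return FirstPcResult(
        loadings=pd.Series(axis, index=au_ids),
        scores=scores,
        subject_means=subject_means,
        explained_variance_ratio=evr,
    )


def bootstrap_band(
    group_series: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap percentile band of a group-mean time course.

    Subjects (rows) are resampled with replacement ``n_boot`` times; the
    per-frame mean of each resample forms the bootstrap distribution whose
    5th/95th percentiles are returned as ``(lower, upper)`` arrays.
    """
    X = np.asarray(group_series, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("group_series must be (subjects, frames)")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    boots = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        boots[b] = np.nanmean(X[rng.integers(0, n, size=n)], axis=0)
    lo, hi = np.percentile(boots, percentiles, axis=0)
    return lo, hi


def correlate_with_covariate(means: pd.DataFrame, covariate) -> pd.DataFrame:
    """Pearson r per AU against a clinical covariate, BH-adjusted.

    Subjects with a missing covariate (or AU mean) are dropped pairwise; the
    number of complete pairs is reported per AU.  A constant covariate gives
    NaN correlations.
    """
    cov = np.asarray(covariate, dtype=float)
    if cov.shape[0] != len(means):
        raise ValueError("covariate length must match subject count")
    rows = []
    for au in means.columns:
        x = means[au].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(cov)
        n_ok = int(ok.sum())
        if n_ok < 3 or np.std(cov[ok]) == 0 or np.std(x[ok]) == 0:
            rows.append((np.nan, np.nan, n_ok))
            continue
        r, p = stats.pearsonr(x[ok], cov[ok])
        rows.append((float(r), float(p), n_ok))
    out = pd.DataFrame(rows, index=means.columns, columns=["r", "p", "n"])
    finite = out["p"].notna()
    q = np.full(len(out), np.nan)
    if finite.any():
        q[finite.to_numpy()] = multipletests(
            out.loc[finite, "p"].to_numpy(), method="fdr_bh"
        )[1]
    out["q"] = q
    return out
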