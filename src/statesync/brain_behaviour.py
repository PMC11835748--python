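"""Linking positive-epoch brain signal to facial expressivity.

Per subject and region, the fMRI trace is regressed on an unconvolved
boxcar marking the positive movie scenes (intercept + boxcar OLS); the
boxcar coefficient is algebraically the mean signal difference between
scene and non-scene volumes.  At the group level, the region coefficient is
regressed on each subject's mean facial activity, and an analysis of
covariance asks whether the slope of that brain-behaviour coupling differs
between melancholic (A) and non-melancholic (B) depression — the
group x covariate interaction F, on 1 and n - 4 degrees of freedom via the
extra sum of squares of the interaction term.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CohortSeries, EpochMask

__all__ = [
    "epoch_boxcar_beta",
    "group_covariation",
    "ancova_interaction",
    "InteractionResult",
]


def epoch_boxcar_beta(cohort: CohortSeries, mask) -> pd.DataFrame:
    """OLS boxcar coefficient per subject and region (no HRF convolution).

    Design: ``signal ~ intercept + boxcar(mask)``.  Requires the mask to
    contain both scene and non-scene volumes, else the design is collinear.
    """
    mvals = mask.values if isinstance(mask, EpochMask) else np.asarray(mask, bool)
    if mvals.shape[0] != cohort.n_volumes:
        raise ValueError("mask length must equal the volume count")
    if mvals.all() or not mvals.any():
        raise ValueError("boxcar design is collinear: mask must contain both levels")
    design = np.column_stack([np.ones(cohort.n_volumes), mvals.astype(float)])
    # one least-squares solve shared by all subjects and regions
    pinv = np.linalg.pinv(design)                              # (2, T)
    betas = np.einsum("pt,ntr->npr", pinv, cohort.data)[:, 1]  # boxcar row -> (n, R)
    return pd.DataFrame(betas, index=cohort.subject_ids, columns=cohort.region_ids)


def group_covariation(betas, facial) -> dict:
    """Simple regression of a region's epoch coefficient on facial means.

    Returns slope, intercept, r, t, p and n over complete pairs.
    """
    y = np.asarray(betas, dtype=float)
    x = np.asarray(facial, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.std(x[ok]) == 0:
        return {"slope": np.nan, "intercept": np.nan, "r": np.nan,
                "t": np.nan, "p": np.nan, "n": int(ok.sum())}
    res = stats.linregress(x[ok], y[ok])
    n = int(ok.sum())
    t = res.rvalue * np.sqrt((n - 2) / max(1e-300, 1 - res.rvalue**2)) if abs(res.rvalue) < 1 else np.inf
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue), "t": float(t), "p": float(res.pvalue), "n": n}


@dataclasses.dataclass
class InteractionResult:
    """Group-specific coupling lines and the interaction test."""

    slopes: dict[str, float]
    intercepts: dict[str, float]
    f_interaction: float
    p_interaction: float
    df: tuple[int, int]
    n_per_group: dict[str, int]
    outliers: list[int]          # indices beyond 2.5 SD of their group mean (reported, kept)


def ancova_interaction(betas, facial, labels) -> InteractionResult:
    """ANCOVA group x covariate interaction on the brain-behaviour coupling.

    Fits ``beta ~ intercept + group + facial + group:facial`` by OLS and
    tests the interaction against the parallel-slopes model by the extra
    sum of squares, F on (1, n - 4) df.  Points beyond 2.5 SD of their
    group's outcome mean are reported but never removed.
    """
    y = np.asarray(betas, dtype=float)
    x = np.asarray(facial, dtype=float)
    lab = np.asarray(labels)
    ok = np.isfinite(x) & np.isfinite(y)
    y, x, lab = y[ok], x[ok], lab[ok]
    groups = np.unique(lab)
    if groups.size != 2:
        raise ValueError("need exactly two groups")
    g = (lab == groups[1]).astype(float)
    for gr in groups:
        if (lab == gr).sum() < 3:
            raise ValueError(f"group {gr} has fewer than 3 complete pairs")
    n = y.shape[0]

    X_full = np.column_stack([np.ones(n), g, x, g * x])
    X_red = X_full[:, :3]
    if np.linalg.matrix_rank(X_full) < 4:
        raise ValueError("rank-deficient ANCOVA design")
    coef_full, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    coef_red, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    ssr_full = float(((y - X_full @ coef_full) ** 2).sum())
    ssr_red = float(((y - X_red @ coef_red) ** 2).sum())
    df2 = n - 4
    if ssr_full <= 0:
        f = np.inf
        p = 0.0
    else:
        f = (ssr_red - ssr_full) / (ssr_full / df2)
        f = max(f, 0.0)
        p = float(stats.f.sf(f, 1, df2))

    b0, b_g, b_x, b_gx = coef_full
    slopes = {str(groups[0]): float(b_x), str(groups[1]): float(b_x + b_gx)}
    intercepts = {str(groups[0]): float(b0), str(groups[1]): float(b0 + b_g)}
    outliers = []
    for gr in groups:
        sel = lab == gr
        mu, sd = y[sel].mean(), y[sel].std(ddof=1)
        if sd > 0:
            outliers.extend(np.flatnonzero(ok)[sel & (np.abs(y - mu) > 2.5 * sd)].tolist())
    return InteractionResult(
        slopes=slopes,
        intercepts=intercepts,
        f_interaction=float(f),
        p_interaction=p,
        df=(1, df2),
        n_per_group={str(gr): int((lab == gr).sum()) for gr in groups},
        outliers=sorted(outliers),
    )
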