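"""Measurement-agreement metrics and group-comparison statistics.

Two scalar time series of the same quantity (e.g. CC lung size measured by
two observers or by observer vs pipeline) are compared with the absolute
systematic error (ASE, the bias at full expiration) and the mean absolute
residual error (MARE, the residual variation once that bias is removed).
Feature tables over subjects are compared between groups with the two-sided
Wilcoxon rank-sum test (exact null distribution for small groups) and
summarized with a significance-masked Pearson correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _check_series(f, g) -> tuple[np.ndarray, np.ndarray]:
    f, g = np.asarray(f, float), np.asarray(g, float)
    if f.ndim != 1 or g.ndim != 1 or len(f) != len(g):
        raise ValueError("series must be 1D and of equal length")
    return f, g


def ase(f, g) -> float:
    """Absolute systematic error: |f(T) − g(T)| (bias at full expiration)."""
    f, g = _check_series(f, g)
    return float(abs(f[-1] - g[-1]))


def mare(f, g) -> float:
    """Mean absolute residual error:
    (1/T)·Σ_t |(f(t)−g(t)) − (f(T)−g(T))| (variation after bias removal)."""
    f, g = _check_series(f, g)
    bias = f[-1] - g[-1]
    return float(np.mean(np.abs((f - g) - bias)))


def rank_sum_test(a, b, exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact null distribution when both groups have <= ``exact_max_n``
    observations and no ties across groups; otherwise the normal
    approximation with tie correction.  Degenerate all-tied data yields 1.0.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    if max(len(a), len(b)) <= exact_max_n and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclass
class GroupComparison:
    """Per-feature group summary plus the masked Pearson matrix."""

    summary: pd.DataFrame          # mean/sd per group, p, significant
    correlation: pd.DataFrame      # Pearson r, nonsignificant cells = NaN
    correlation_p: pd.DataFrame


def group_stats(features: pd.DataFrame, groups: pd.Series | np.ndarray,
                alpha: float = 0.05) -> GroupComparison:
    """Compare every numeric feature column between two groups.

    Returns per-feature group means (sd), the two-sided rank-sum p-value
    and a 5%-level significance flag, sorted by descending p; plus the
    Pearson correlation matrix over all feature pairs with non-significant
    (p >= alpha) cells masked to NaN.
    """
    groups = pd.Series(np.asarray(groups), index=features.index)
    names = pd.unique(groups)
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(names)}")
    ga, gb = names
    rows = []
    for col in features.columns:
        x = features[col].astype(float)
        a = x[groups == ga].dropna().to_numpy()
        b = x[groups == gb].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"feature {col}: fewer than 2 subjects per group", stacklevel=2)
            p = float("nan")
        else:
            p = rank_sum_test(a, b)
        flagged = np.ptp(np.concatenate([a, b])) == 0 if len(a) and len(b) else True
        rows.append({
            "feature": col,
            f"mean_{ga}": a.mean() if len(a) else np.nan,
            f"sd_{ga}": a.std(ddof=1) if len(a) > 1 else np.nan,
            f"mean_{gb}": b.mean() if len(b) else np.nan,
            f"sd_{gb}": b.std(ddof=1) if len(b) > 1 else np.nan,
            "p": p,
            "significant": bool(p < alpha) if np.isfinite(p) else False,
            "degenerate": bool(flagged),
        })
    summary = pd.DataFrame(rows).sort_values("p", ascending=False,
                                             kind="stable").reset_index(drop=True)

    cols = list(features.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            if j <= i:
                continue
            xy = features[[ci, cj]].astype(float).dropna()
            if len(xy) < 3 or xy[ci].nunique() < 2 or xy[cj].nunique() < 2:
                rij, pij = np.nan, 1.0
            else:
                rij, pij = stats.pearsonr(xy[ci], xy[cj])
            r.loc[ci, cj] = r.loc[cj, ci] = rij
            pmat.loc[ci, cj] = pmat.loc[cj, ci] = pij
    masked = r.where(pmat < alpha)
    np.fill_diagonal(masked.values, 1.0)
    return GroupComparison(summary, masked, pmat)
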