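"""Primitive statistics used throughout the analysis.

These are the building blocks of the differential-expression and pattern
stages: the Wilcoxon/Mann-Whitney rank-sum test, Benjamini-Hochberg FDR,
log2 fold change on linear-scale means, one-way ANOVA and Welch's t.
Established implementations (scipy, statsmodels) sit behind each surface;
the functions here fix conventions (U orientation, exact-vs-asymptotic
crossover, pseudocounts) that the rest of the package relies on.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "rank_sum_test",
    "rank_sum_matrix",
    "bh_fdr",
    "log2fc",
    "anova_oneway",
    "welch_t",
]

#: below this combined sample size an exact rank-sum p-value is computed
#: (when the pooled data are tie-free); above it the normal approximation
#: with tie and continuity correction is used.
EXACT_CROSSOVER = 16


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic counting x-over-y wins, ties counted half."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2.0)


def rank_sum_test(x, y, *, exact_crossover: int = EXACT_CROSSOVER) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Parameters
    ----------
    x, y
        The two samples; each must be non-empty.
    exact_crossover
        Combined sample size at or below which the exact null
        distribution is used, provided the pooled values are tie-free.

    Returns
    -------
    (U, p)
        ``U`` counts pairs where x exceeds y, ties counted half, so
        ``U_xy + U_yx == len(x) * len(y)``. ``p`` is two-sided: exact for
        small tie-free samples, otherwise the normal approximation with
        tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test requires both groups to be non-empty")
    u = _mann_whitney_u(x, y)
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if x.size + y.size <= exact_crossover and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):  # all values tied -> no evidence either way
        p = 1.0
    return u, min(p, 1.0)


def rank_sum_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise rank-sum tests for two spot-by-gene matrices.

    Vectorized asymptotic path (tie + continuity corrected); intended for
    the group sizes seen in region-stratified differential expression.
    Columns where every pooled value ties get p = 1.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValidationError("rank_sum_matrix expects two 2-D arrays with equal gene axes")
    if X.shape[0] < 1 or Y.shape[0] < 1:
        raise ValidationError("rank_sum_matrix requires both groups to be non-empty")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.mannwhitneyu(
            X, Y, alternative="two-sided", method="asymptotic", axis=0
        )
    u = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, np.clip(p, np.nextafter(0, 1), 1.0))
    return u, p


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; every p must lie in (0, 1].
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValidationError("bh_fdr requires all p-values in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2fc(mean_from: float, mean_to: float, pseudocount: float = 1e-9) -> float:
    """log2 fold change of two non-negative linear-scale means.

    The pseudocount guards the zero-mean case; with the default 1e-9 it is
    negligible for any expressed gene.
    """
    if mean_from < 0 or mean_to < 0:
        raise ValidationError("log2fc requires non-negative means")
    return float(np.log2((mean_to + pseudocount) / (mean_from + pseudocount)))


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p across ``groups``.

    Degenerate input (zero variance everywhere) yields ``(inf, 0.0)`` so
    that such genes sort first deterministically; callers warn on it.
    """
    if len(groups) < 2:
        raise ValidationError("anova_oneway requires at least two groups")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValidationError("anova_oneway requires >= 2 observations per group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # identical everywhere: F is 0/0; define as no effect
        return 0.0, 1.0
    within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    if within == 0.0:
        return float("inf"), 0.0
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def welch_t(a, b) -> tuple[float, float]:
    """Welch's two-sample t (unequal variances), ``b`` minus ``a``.

    Returns ``(t, p)``; degenerate zero-variance equal-mean input gives
    ``(0.0, 1.0)``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch_t requires >= 2 observations per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        sign = 1.0 if b.mean() > a.mean() else -1.0
        return sign * float("inf"), 0.0
    t, p = sps.ttest_ind(b, a, equal_var=False)
    return float(t), float(p)
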