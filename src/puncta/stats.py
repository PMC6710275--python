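"""Group-comparison statistics for per-sample scores.

Small-cohort comparisons (e.g. H-scores of 4 control vs 4 disease
samples) use an exact Mann-Whitney U test: the two-sided p-value is
obtained by enumerating all C(n_a + n_b, n_a) assignments of the pooled
mid-ranks, doubling the one-sided tail and capping at 1.  Larger groups
fall back to the tie-corrected normal approximation.  Pearson correlation
uses the t-transform with n - 2 degrees of freedom, and the extreme-
outlier filter removes points beyond 1.5 interquartile ranges outside the
quartiles (type-7 / linear-interpolation quartiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as sps

#: largest pooled size for which the exact enumeration is used by default
EXACT_ENUMERATION_LIMIT = 12


@dataclass
class GroupComparison:
    group_a: list[float]
    group_b: list[float]
    u_statistic: float
    p_two_sided: float
    method: str


@dataclass
class CorrelationResult:
    r: float
    p_two_sided: float
    n: int


def _u_from_ranks(rank_sum_a: float, n_a: int) -> float:
    return rank_sum_a - n_a * (n_a + 1) / 2


def mann_whitney_exact(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    ``method``: "exact" enumerates every rank arrangement (ties handled by
    mid-ranks over the observed pooled multiset); "asymptotic" uses the
    tie-corrected normal approximation; "auto" picks exact when
    n_a + n_b <= 12.
    """
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        method = "exact" if n_a + n_b <= EXACT_ENUMERATION_LIMIT else "asymptotic"

    pooled = np.array(a + b)
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    u_obs = _u_from_ranks(ranks[:n_a].sum(), n_a)

    if method == "exact":
        n = n_a + n_b
        mean_u = n_a * n_b / 2
        tol = 1e-9
        tail = 0
        total = comb(n, n_a)
        for idx in combinations(range(n), n_a):
            u = _u_from_ranks(ranks[list(idx)].sum(), n_a)
            if u_obs >= mean_u:
                tail += u >= u_obs - tol
            else:
                tail += u <= u_obs + tol
        p = min(1.0, 2 * tail / total)
    elif method == "asymptotic":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        group_a=a,
        group_b=b,
        u_statistic=float(u_obs),
        p_two_sided=float(min(1.0, max(p, 0.0))),
        method=method,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with two-sided p from Student-t(n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_two_sided=float(res.pvalue), n=n)


def remove_extreme_outliers(
    values: Sequence[float], iqr_multiplier: float = 1.5
) -> list[float]:
    """Drop values beyond ``iqr_multiplier`` × IQR outside the quartiles.

    Quartiles use linear interpolation (type-7).  Single pass by contract:
    the fences are computed once on the input and not re-derived after
    removal.  Fewer than 4 values: returned unchanged with a warning.
    """
    vals = [float(v) for v in values]
    if len(vals) < 4:
        warnings.warn(
            "fewer than 4 values: outlier fences are unreliable, returning "
            "the input unchanged",
            stacklevel=2,
        )
        return vals
    q1, q3 = np.percentile(vals, [25, 75])  # 'linear' = type-7
    iqr = q3 - q1
    lo = q1 - iqr_multiplier * iqr
    hi = q3 + iqr_multiplier * iqr
    return [v for v in vals if lo <= v <= hi]
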