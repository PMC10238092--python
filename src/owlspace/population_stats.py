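"""Group-level statistics for neuron populations.

Pooled Pearson regressions of best frequency on best ITD, pooled-variance
t-tests comparing regression slopes and intercepts between groups,
Mann-Whitney U on frontal best frequencies, and the rank-biserial effect
size derived from U.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RegressionResult",
    "RegressionComparison",
    "GroupComparison",
    "pearson_regression",
    "compare_slopes",
    "compare_intercepts",
    "mann_whitney_u",
    "rank_biserial",
    "compare_groups",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class RegressionComparison:
    a: RegressionResult
    b: RegressionResult
    t_slope: float
    p_slope: float
    t_intercept: float
    p_intercept: float
    df: int


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n1: int
    n2: int
    u: float  # min(U1, U2)
    p_value: float
    rank_biserial_r: float  # |1 - 2U/(n1 n2)|, 0..1
    direction: int  # +1 if group a tends larger, -1 if smaller, 0 if tied


def pearson_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x; p from the correlation t-statistic
    with n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression is degenerate")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def _ols_parts(x: np.ndarray, y: np.ndarray):
    n = x.size
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    return n, xbar, sxx, slope, intercept, sse


def compare_slopes(
    xa: Sequence[float],
    ya: Sequence[float],
    xb: Sequence[float],
    yb: Sequence[float],
) -> RegressionComparison:
    """Two-regression pooled-variance t-tests on slope and intercept.

    t = (b_A - b_B) / SE with the residual variance pooled across the two
    fits; df = n_A + n_B - 4; two-sided p.
    """
    xa = np.asarray(xa, dtype=float)
    ya = np.asarray(ya, dtype=float)
    xb = np.asarray(xb, dtype=float)
    yb = np.asarray(yb, dtype=float)
    ra = pearson_regression(xa, ya)
    rb = pearson_regression(xb, yb)
    na, xbar_a, sxx_a, ba, ia, sse_a = _ols_parts(xa, ya)
    nb, xbar_b, sxx_b, bb, ib, sse_b = _ols_parts(xb, yb)
    df = na + nb - 4
    if df < 1:
        raise ValueError("not enough observations for a slope comparison")
    s2 = (sse_a + sse_b) / df
    se_slope = np.sqrt(s2 * (1.0 / sxx_a + 1.0 / sxx_b))
    t_slope = (ba - bb) / se_slope
    p_slope = 2.0 * stats.t.sf(abs(t_slope), df)
    se_int = np.sqrt(
        s2 * (1.0 / na + xbar_a**2 / sxx_a + 1.0 / nb + xbar_b**2 / sxx_b)
    )
    t_int = (ia - ib) / se_int
    p_int = 2.0 * stats.t.sf(abs(t_int), df)
    return RegressionComparison(
        a=ra,
        b=rb,
        t_slope=float(t_slope),
        p_slope=float(p_slope),
        t_intercept=float(t_int),
        p_intercept=float(p_int),
        df=int(df),
    )


def compare_intercepts(
    xa: Sequence[float],
    ya: Sequence[float],
    xb: Sequence[float],
    yb: Sequence[float],
) -> tuple[float, float, int]:
    """(t, p, df) for the intercept difference; see :func:`compare_slopes`."""
    cmp = compare_slopes(xa, ya, xb, yb)
    return cmp.t_intercept, cmp.p_intercept, cmp.df


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (min(U1, U2), p).

    Ties contribute 0.5 to U. The p-value is exact for small tie-free
    samples (n1*n2 <= 400) and a tie- and continuity-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)
    return u, float(res.pvalue)


def rank_biserial(u: float, n1: int, n2: int) -> float:
    """Rank-biserial effect size r = |1 - 2U/(n1*n2)| on a 0-1 scale
    (1 = no overlap between groups)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be positive")
    if not (0.0 <= u <= n1 * n2):
        raise ValueError(f"U={u} outside [0, {n1 * n2}]")
    return abs(1.0 - 2.0 * u / (n1 * n2))


def compare_groups(
    a: Sequence[float], b: Sequence[float], label_a: str = "a", label_b: str = "b"
) -> GroupComparison:
    """Mann-Whitney U plus rank-biserial effect size for two value sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u, p = mann_whitney_u(a, b)
    r = rank_biserial(u, a.size, b.size)
    # direction from U1 relative to its null mean
    u1 = float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic
    )
    mid = a.size * b.size / 2.0
    direction = 0 if u1 == mid else (1 if u1 > mid else -1)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n1=int(a.size),
        n2=int(b.size),
        u=u,
        p_value=p,
        rank_biserial_r=r,
        direction=direction,
    )
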