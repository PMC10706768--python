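"""Biovar-level statistics: quadrants, proportions, t tests, correlations.

Genes (and later GO groups) are partitioned into four quadrants by
whether a metric is above or below its pool average in each biovar:
I = above in both (Ori+Off+), II = above only in officinalis (Ori-Off+),
III = above only in orientalis (Ori+Off-), IV = below in both
(Ori-Off-).  "Above" is strict; a value exactly at the mean counts as
below, so the rule is deterministic.

Pooled summaries are reported as mean +/- SE with Student's t for
between-pool comparisons; polymorphic-gene fractions carry the binomial
standard error sqrt(p(1-p)/n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "QUADRANTS",
    "StatResult",
    "p0_band",
    "assign_quadrant",
    "proportion_with_se",
    "compare_proportions",
    "compare_means",
    "mean_with_se",
    "pearson_correlation",
    "compare_correlations",
]

QUADRANTS = ("I", "II", "III", "IV")


def p0_band(p: float | None) -> str:
    """Render a p-value as the probability bands used in the summaries."""
    if p is None or math.isnan(p):
        return "n/a"
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return "<0.01"
    if p < 0.05:
        return "<0.05"
    if p < 0.10:
        return "0.05<P0<0.10"
    return ">0.10"


@dataclass
class StatResult:
    """An estimate with its SE and (optionally) a Student test against a null."""

    estimate: float
    standard_error: float
    n: int | None = None
    t: float | None = None
    p_value: float | None = None
    df: float | None = None

    @property
    def band(self) -> str:
        return p0_band(self.p_value if self.p_value is not None else math.nan)


def assign_quadrant(
    value_ori: float,
    value_off: float,
    mean_ori: float,
    mean_off: float,
) -> str:
    """Quadrant of a gene given its per-biovar values and the pool means."""
    for v in (value_ori, value_off, mean_ori, mean_off):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError("quadrant undefined for NaN input")
    hi_ori = value_ori > mean_ori
    hi_off = value_off > mean_off
    if hi_ori and hi_off:
        return "I"
    if not hi_ori and hi_off:
        return "II"
    if hi_ori and not hi_off:
        return "III"
    return "IV"


def proportion_with_se(k: int, n: int) -> StatResult:
    """Binomial proportion k/n with SE sqrt(p(1-p)/n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    p = k / n
    return StatResult(p, math.sqrt(p * (1 - p) / n), n=n)


def _t_test(diff: float, se: float, df: float) -> tuple[float, float]:
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, p


def compare_proportions(r1: StatResult, r2: StatResult) -> StatResult:
    """Student's t for the difference of two proportions.

    t = (p1 - p2)/sqrt(SE1^2 + SE2^2) on n1+n2-2 degrees of freedom.
    Two identical proportions with zero SEs are reported as no
    difference (t undefined, p = 1).
    """
    if r1.n is None or r2.n is None:
        raise ValueError("proportions must carry their sample sizes")
    diff = r1.estimate - r2.estimate
    pooled = math.hypot(r1.standard_error, r2.standard_error)
    df = r1.n + r2.n - 2
    if pooled == 0.0:
        if diff == 0.0:
            return StatResult(diff, 0.0, n=r1.n + r2.n, t=None, p_value=1.0, df=df)
        # degenerate proportions (0/n vs n/n): difference is certain
        return StatResult(
            diff, 0.0, n=r1.n + r2.n,
            t=math.copysign(math.inf, diff), p_value=0.0, df=df,
        )
    t, p = _t_test(diff, pooled, df)
    return StatResult(diff, pooled, n=r1.n + r2.n, t=t, p_value=p, df=df)


def compare_means(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> StatResult:
    """Student's t for the difference of two pooled means (plug-in SEs)."""
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 in both pools")
    diff = mean1 - mean2
    pooled = math.hypot(se1, se2)
    df = n1 + n2 - 2
    if pooled == 0.0:
        return StatResult(diff, 0.0, n=n1 + n2, t=None, p_value=None, df=df)
    t, p = _t_test(diff, pooled, df)
    return StatResult(diff, pooled, n=n1 + n2, t=t, p_value=p, df=df)


def mean_with_se(values) -> StatResult:
    """Mean over per-gene values with SE = sample SD / sqrt(n); NaNs dropped."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if n == 0:
        raise ValueError("no defined values")
    se = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return StatResult(float(arr.mean()), se, n=n)


def pearson_correlation(x, y) -> StatResult:
    """Pearson r with t = r sqrt((n-2)/(1-r^2)); pairs with NaN dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired values")
    if x.std() == 0.0 or y.std() == 0.0:
        return StatResult(math.nan, math.nan, n=n)
    r = float(np.corrcoef(x, y)[0, 1])
    se = math.sqrt((1 - r**2) / (n - 2)) if abs(r) < 1 else 0.0
    if abs(r) >= 1.0:
        return StatResult(r, 0.0, n=n, t=math.inf, p_value=0.0, df=n - 2)
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return StatResult(r, se, n=n, t=t, p_value=p, df=n - 2)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> StatResult:
    """Fisher z comparison of two independent correlations."""
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 in both samples")
    if max(abs(r1), abs(r2)) >= 1.0:
        return StatResult(math.nan, math.nan, n=n1 + n2)
    z1, z2 = math.atanh(r1), math.atanh(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return StatResult(z1 - z2, se, n=n1 + n2, t=z, p_value=p)
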