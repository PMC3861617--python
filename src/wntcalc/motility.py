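"""Scratch-wound closure rates and slope comparison.

Wound width shrinks roughly linearly while cells migrate in; the closure
rate is minus the OLS slope of width on time. Two conditions are compared
with the extra-sum-of-squares F-test: the full model fits a slope and
intercept per condition, the reduced model shares one slope, and

    F = ((RSS_reduced - RSS_full) / 1) / (RSS_full / df_full)

with df_full = n_a + n_b - 4, referred to the F(1, df_full) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .stats import ols

__all__ = ["WoundSeries", "ClosureRate", "SlopeComparison",
           "fit_closure_rate", "compare_slopes"]


@dataclass(frozen=True)
class WoundSeries:
    """Wound widths (μm) at imaging times (h) for one condition."""

    condition: str
    times: tuple
    widths: tuple

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.widths, dtype=float)
        if t.size != w.size:
            raise ValueError("times and widths must have equal length")
        if t.size < 4:
            raise ValueError("need at least 4 time points")
        if np.any(w < 0):
            raise ValueError("widths must be non-negative")


@dataclass(frozen=True)
class ClosureRate:
    """Closure rate (μm/h) = −slope of the width-vs-time regression."""

    condition: str
    rate: float
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    rss: float


def fit_closure_rate(series: WoundSeries) -> ClosureRate:
    """Ordinary least squares of width on time; rate = −slope."""
    fit = ols(series.times, series.widths)
    return ClosureRate(condition=series.condition, rate=-fit.slope,
                       slope=fit.slope, intercept=fit.intercept,
                       slope_se=fit.slope_se, r_squared=fit.r_squared,
                       rss=fit.rss)


@dataclass(frozen=True)
class SlopeComparison:
    """Extra-sum-of-squares F-test of slope equality between two series."""

    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    rss_full: float
    rss_reduced: float


def compare_slopes(series_a: WoundSeries,
                   series_b: WoundSeries) -> SlopeComparison:
    """Test whether two wound series close at the same rate.

    Full model: separate slope and intercept per condition. Reduced model:
    common slope, separate intercepts. With both residual sums of squares
    zero (exact, noiseless lines) F is infinite and p is reported as 0.
    """
    ta = np.asarray(series_a.times, dtype=float)
    wa = np.asarray(series_a.widths, dtype=float)
    tb = np.asarray(series_b.times, dtype=float)
    wb = np.asarray(series_b.widths, dtype=float)
    if np.ptp(ta) == 0 or np.ptp(tb) == 0:
        raise ValueError("degenerate design: constant times")

    rss_full = ols(ta, wa).rss + ols(tb, wb).rss
    # reduced model: common slope via centred pooled regression
    ya = wa - wa.mean()
    yb = wb - wb.mean()
    xa = ta - ta.mean()
    xb = tb - tb.mean()
    common_slope = float((xa @ ya + xb @ yb) / (xa @ xa + xb @ xb))
    rss_reduced = float(np.sum((ya - common_slope * xa) ** 2)
                        + np.sum((yb - common_slope * xb) ** 2))

    df_den = ta.size + tb.size - 4
    if df_den < 1:
        raise ValueError("not enough points for the F-test")
    if rss_full <= 0:
        extra = rss_reduced - rss_full
        f = float("inf") if extra > 0 else 0.0
        p = 0.0 if extra > 0 else 1.0
    else:
        f = max(0.0, (rss_reduced - rss_full)) / (rss_full / df_den)
        p = float(sps.f.sf(f, 1, df_den))
    return SlopeComparison(f_statistic=float(f), p_value=p, df_num=1,
                           df_den=int(df_den), rss_full=float(rss_full),
                           rss_reduced=float(rss_reduced))
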