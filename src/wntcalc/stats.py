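"""Shared statistical primitives: Mann-Whitney U, OLS, slope F-test.

Every hypothesis test in the package routes through this module so that the
testing conventions (two-sided by default, exact small-sample p-values,
mid-rank tie handling) are applied uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "OLSResult", "mann_whitney_u", "ols"]

#: combined sample size at or below which the exact null distribution of U is
#: used (ties force the approximate path with mid-ranks regardless)
EXACT_CUTOFF = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    method: str  # "exact" | "approximate"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class OLSResult:
    """Simple linear regression summary."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    rss: float
    r_squared: float
    n: int


def mann_whitney_u(x, y, alternative: str = "two_sided") -> TestResult:
    """Mann-Whitney U test of ``x`` versus ``y``.

    The p-value is exact (full enumeration of rank arrangements) when the
    combined sample size is at most ``EXACT_CUTOFF`` and there are no ties;
    otherwise the normal approximation with tie and continuity correction is
    used.

    Parameters
    ----------
    x, y
        The two samples; both must be non-empty.
    alternative
        ``"two_sided"`` (default), ``"less"`` or ``"greater"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}.get(
        alternative
    )
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")

    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = (x.size + y.size) <= EXACT_CUTOFF and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alt, method=method,
                           use_continuity=True)
    p = min(1.0, float(res.pvalue))
    # U at the centre of the (symmetric) null: two-sided p is 1 by symmetry,
    # which the continuity-corrected normal approximation understates
    if alt == "two-sided" and float(res.statistic) == x.size * y.size / 2.0:
        p = 1.0
    return TestResult(
        statistic=float(res.statistic),
        p_value=p,
        method="exact" if exact else "approximate",
    )


def ols(x, y) -> OLSResult:
    """Ordinary least squares of ``y`` on ``x`` (closed form, one predictor).

    Requires at least 3 points and a non-constant predictor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope undefined")

    fit = sps.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    rss = float(resid @ resid)
    return OLSResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        intercept_se=float(fit.intercept_stderr),
        rss=rss,
        r_squared=float(fit.rvalue) ** 2,
        n=int(x.size),
    )
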