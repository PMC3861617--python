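"""Dose-response analysis of dwell time versus ligand concentration.

Two candidate curves describe how the calcium-transient dwell time responds
to increasing ligand concentration:

* first-order decay ``y0 + A1*exp(-x/t1)`` — dwell time *falls* with
  concentration (negative cooperativity of ligand-receptor binding); the
  rate constant is ``k = 1/t1``;
* Michaelis-Menten ``DTmax * C / (K_half + C)`` — dwell time rises and
  saturates, the classical single-site behaviour.

``diagnose`` decides between them (or a flat/indeterminate response) from
adjacent-concentration Mann-Whitney comparisons, with both fits attached as
supporting evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .stats import TestResult, mann_whitney_u

__all__ = [
    "ConcentrationSeries",
    "DecayFit",
    "MMFit",
    "DoseDiagnosis",
    "fit_first_order_decay",
    "fit_michaelis_menten",
    "diagnose",
]


@dataclass(frozen=True)
class ConcentrationSeries:
    """Replicate dwell times (s) at each ligand concentration (ng/ml)."""

    ligand: str
    concentrations: tuple    # ascending, ng/ml
    observations: tuple      # one tuple of replicates per concentration

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if c.size != len(self.observations):
            raise ValueError("one replicate set per concentration required")
        if c.size >= 2 and np.any(np.diff(c) < 0):
            raise ValueError("concentrations must be ascending")
        for obs in self.observations:
            if len(obs) == 0:
                raise ValueError("empty replicate set")
            if np.any(np.asarray(obs, dtype=float) < 0):
                raise ValueError("observations must be non-negative")

    def means(self) -> np.ndarray:
        return np.array([np.mean(o) for o in self.observations])


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit ``y0 + A1*exp(-x/t1)``; rate constant k = 1/t1."""

    y0: float
    A1: float
    t1: float
    rss: float
    converged: bool

    @property
    def k(self) -> float:
        return 1.0 / self.t1 if self.t1 > 0 else float("nan")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.y0 + self.A1 * np.exp(-x / self.t1)


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten fit ``dt_max * C / (k_half + C)``."""

    dt_max: float
    k_half: float
    rss: float
    converged: bool

    def predict(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.dt_max * c / (self.k_half + c)


@dataclass(frozen=True)
class DoseDiagnosis:
    """Dose-response mode call with supporting fits and pairwise tests."""

    mode: str                        # negative_cooperative | michaelis_menten
    #                                # | flat/indeterminate
    decay_fit: DecayFit | None
    mm_fit: MMFit | None
    pairwise: tuple = ()             # ((c_lo, c_hi, TestResult), ...)
    preferred_fit: str = ""          # "decay" | "mm" | ""


def _decay(x, y0, a1, t1):
    return y0 + a1 * np.exp(-x / t1)


def fit_first_order_decay(series: ConcentrationSeries,
                          on_means: bool = True) -> DecayFit:
    """Least-squares first-order decay on per-concentration means.

    Set ``on_means=False`` to fit all replicates. Requires >= 3 distinct
    concentrations (three parameters). Non-convergence and unidentifiable
    amplitude (near-constant data) are flagged, never raised.
    """
    c = np.asarray(series.concentrations, dtype=float)
    if np.unique(c).size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if on_means:
        x, y = c, series.means()
    else:
        x = np.concatenate([np.full(len(o), ci)
                            for ci, o in zip(c, series.observations)])
        y = np.concatenate([np.asarray(o, float)
                            for o in series.observations])

    spread = float(np.ptp(y))
    if spread < 1e-12 * max(1.0, abs(float(np.mean(y)))):
        # constant response: A1 ~ 0 and t1 unidentifiable
        return DecayFit(y0=float(np.mean(y)), A1=0.0, t1=float("nan"),
                        rss=float(np.sum((y - np.mean(y)) ** 2)),
                        converged=False)
    p0 = [float(np.min(y)), max(spread, 1e-9), float(np.median(x))]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _decay, x, y, p0=p0,
                bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=10000)
    except (RuntimeError, ValueError):
        return DecayFit(y0=p0[0], A1=p0[1], t1=p0[2], rss=float("nan"),
                        converged=False)
    resid = y - _decay(x, *popt)
    return DecayFit(y0=float(popt[0]), A1=float(popt[1]), t1=float(popt[2]),
                    rss=float(resid @ resid), converged=True)


def _mm(c, dt_max, k_half):
    return dt_max * c / (k_half + c)


def fit_michaelis_menten(series: ConcentrationSeries,
                         on_means: bool = True) -> MMFit:
    """Least-squares Michaelis-Menten fit on per-concentration means."""
    c = np.asarray(series.concentrations, dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("need >= 2 distinct concentrations")
    if on_means:
        x, y = c, series.means()
    else:
        x = np.concatenate([np.full(len(o), ci)
                            for ci, o in zip(c, series.observations)])
        y = np.concatenate([np.asarray(o, float)
                            for o in series.observations])
    p0 = [max(float(np.max(y)), 1e-9), float(np.median(x))]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_mm, x, y, p0=p0,
                                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                                maxfev=10000)
    except (RuntimeError, ValueError):
        return MMFit(dt_max=p0[0], k_half=p0[1], rss=float("nan"),
                     converged=False)
    resid = y - _mm(x, *popt)
    return MMFit(dt_max=float(popt[0]), k_half=float(popt[1]),
                 rss=float(resid @ resid), converged=True)


def diagnose(series: ConcentrationSeries, alpha: float = 0.05) -> DoseDiagnosis:
    """Call the dose-response mode from adjacent-concentration comparisons.

    Adjacent concentration pairs are compared with a two-sided Mann-Whitney
    test (uncorrected). No significant pair → ``flat/indeterminate``. At
    least one significant decrease and no significant increase →
    ``negative_cooperative``. Significant increase(s) only →
    ``michaelis_menten``. Mixed directions → ``flat/indeterminate``. Both
    candidate fits are attached; the lower-RSS one is named as support.
    """
    c = np.asarray(series.concentrations, dtype=float)
    if np.unique(c).size < 3:
        raise ValueError("need >= 3 distinct concentrations to diagnose")
    if any(len(o) < 3 for o in series.observations):
        raise ValueError("need >= 3 replicates per concentration")

    pairwise = []
    sig_down = sig_up = 0
    for i in range(len(c) - 1):
        lo, hi = series.observations[i], series.observations[i + 1]
        res: TestResult = mann_whitney_u(lo, hi, alternative="two_sided")
        pairwise.append((float(c[i]), float(c[i + 1]), res))
        if res.p_value < alpha:
            if np.mean(hi) < np.mean(lo):
                sig_down += 1
            else:
                sig_up += 1

    decay = fit_first_order_decay(series)
    mm = fit_michaelis_menten(series)
    if decay.converged and mm.converged:
        preferred = "decay" if decay.rss <= mm.rss else "mm"
    elif decay.converged:
        preferred = "decay"
    elif mm.converged:
        preferred = "mm"
    else:
        preferred = ""

    if sig_down == 0 and sig_up == 0:
        mode = "flat/indeterminate"
    elif sig_down > 0 and sig_up == 0:
        mode = "negative_cooperative"
    elif sig_up > 0 and sig_down == 0:
        mode = "michaelis_menten"
    else:
        mode = "flat/indeterminate"
    return DoseDiagnosis(mode=mode, decay_fit=decay, mm_fit=mm,
                         pairwise=tuple(pairwise), preferred_fit=preferred)
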