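"""Waveform kinetics: Gaussian fits, 10%/90% time constants, onsets, wave speed.

The calcium waveform is the per-sample Fluo-4/FuraRed intensity ratio of one
region of interest (ROI). A single Gaussian ``y0 + A*exp(-(t-t0)^2/(2*sigma^2))``
is fitted to the ratio; the fitted baseline ``y0`` and amplitude ``A`` set two
threshold levels at 10% and 90% of the amplitude, and the crossing times of
those levels — located on the *measured* ratio by linear interpolation, so that
asymmetric rise/fall limbs keep their distinct timing — define the time
constants:

* rise time  = first 90% up-crossing − first 10% up-crossing
* dwell time = last 90% down-crossing − first 90% up-crossing
  (how long the signal is sustained at peak amplitude)
* fall time  = last 10% down-crossing − last 90% down-crossing

Amplitude is reported as ``max(ratio) − y0`` (the peak of the waveform above
baseline), with the fitted ``A`` kept alongside for quality control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stats import ols

__all__ = [
    "RatioTrace",
    "GaussianFit",
    "TimeConstants",
    "OnsetResult",
    "FrontSpeed",
    "compute_ratio",
    "fit_gaussian",
    "extract_time_constants",
    "detect_onset",
    "onset_lag",
    "estimate_front_speed",
    "read_trace_table",
    "analyze_traces",
]

# level fractions of the amplitude used for thresholding
LOWER_FRACTION = 0.10
UPPER_FRACTION = 0.90
# a transient is "detected" when fitted A >= DETECTION_K * robust noise SD of
# the pre-stimulus (first 10%) segment, with an absolute floor for noiseless
# synthetic traces whose pre-stimulus SD is exactly zero
DETECTION_K = 5.0
DETECTION_FLOOR = 1e-3
# fraction of the trace treated as pre-stimulus baseline for noise estimation
BASELINE_FRACTION = 0.10


@dataclass(frozen=True)
class RatioTrace:
    """Time-aligned two-channel intensities and their ratio for one ROI.

    ``time`` must be strictly increasing and (nominally) uniformly sampled;
    ``furared`` must be strictly positive wherever the ratio is used.
    """

    time: np.ndarray
    fluo4: np.ndarray
    furared: np.ndarray
    ratio: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        fluo4 = np.asarray(self.fluo4, dtype=float)
        furared = np.asarray(self.furared, dtype=float)
        if not (time.size == fluo4.size == furared.size):
            raise ValueError("time and channel arrays must have equal length")
        if time.size >= 2 and np.any(np.diff(time) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "fluo4", fluo4)
        object.__setattr__(self, "furared", furared)
        if self.ratio is None:
            object.__setattr__(self, "ratio", compute_ratio(fluo4, furared))
        else:
            object.__setattr__(self, "ratio",
                               np.asarray(self.ratio, dtype=float))

    def __len__(self) -> int:
        return self.time.size

    @property
    def sample_interval(self) -> float:
        return float(np.median(np.diff(self.time)))

    @classmethod
    def from_ratio(cls, time, ratio) -> "RatioTrace":
        """Build a trace directly from a ratio series (unit FuraRed channel)."""
        ratio = np.asarray(ratio, dtype=float)
        return cls(time=np.asarray(time, dtype=float), fluo4=ratio,
                   furared=np.ones_like(ratio), ratio=ratio)


def compute_ratio(fluo4, furared) -> np.ndarray:
    """Element-wise Fluo-4 / FuraRed ratio.

    Raises ``ValueError`` if the channels differ in length or the FuraRed
    channel is not strictly positive (the ratio would be undefined).
    """
    fluo4 = np.asarray(fluo4, dtype=float)
    furared = np.asarray(furared, dtype=float)
    if fluo4.shape != furared.shape:
        raise ValueError("channels must have equal length")
    if np.any(furared <= 0):
        raise ValueError("FuraRed channel must be strictly positive")
    return fluo4 / furared


@dataclass(frozen=True)
class GaussianFit:
    """Least-squares single-Gaussian fit ``y0 + A*exp(-(t-t0)^2/(2 sigma^2))``."""

    y0: float
    A: float
    t0: float
    sigma: float
    rss: float
    converged: bool

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.y0 + self.A * np.exp(-((t - self.t0) ** 2)
                                         / (2.0 * self.sigma ** 2))


@dataclass(frozen=True)
class TimeConstants:
    """Threshold-crossing time constants of one transient.

    ``crossings`` holds (lower-up, upper-up, upper-down, lower-down) times in
    seconds. ``detected`` is False (and times are NaN) when no transient above
    the detection threshold is present; flags may include ``"no_transient"``,
    ``"multi_peak"`` and ``"not_converged"``.
    """

    rise_time: float
    dwell_time: float
    fall_time: float
    amplitude: float
    crossings: tuple
    detected: bool = True
    flags: tuple = ()


NO_TRANSIENT = TimeConstants(
    rise_time=float("nan"), dwell_time=float("nan"), fall_time=float("nan"),
    amplitude=0.0, crossings=(float("nan"),) * 4, detected=False,
    flags=("no_transient",),
)


@dataclass(frozen=True)
class OnsetResult:
    """Time at which the ratio first rises through the onset level."""

    onset_time: float
    detected: bool


def _robust_sd(x: np.ndarray) -> float:
    """1.4826 * median absolute deviation (robust Gaussian SD)."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def _gauss(t, y0, A, t0, sigma):
    return y0 + A * np.exp(-((t - t0) ** 2) / (2.0 * sigma ** 2))


def fit_gaussian(trace: RatioTrace) -> GaussianFit:
    """Fit a single Gaussian to the ratio waveform.

    Initialisation: ``y0`` from the median of the first 10% of samples,
    ``A = max − y0``, ``t0`` at the argmax and ``sigma`` from the full width at
    half maximum. Optimizer failure is reported as ``converged=False``, never
    raised.
    """
    if len(trace) < 10:
        raise ValueError("need at least 10 samples to fit")
    t, y = trace.time, trace.ratio
    n_base = max(3, int(np.ceil(BASELINE_FRACTION * y.size)))
    y0_init = float(np.median(y[:n_base]))
    a_init = float(np.max(y) - y0_init)
    t0_init = float(t[np.argmax(y)])
    sigma_init = _fwhm_sigma(t, y, y0_init, a_init)
    duration = float(t[-1] - t[0])

    if a_init <= 0:
        # flat or decreasing trace: report the degenerate fit directly
        resid = y - np.mean(y)
        return GaussianFit(y0=float(np.mean(y)), A=0.0, t0=t0_init,
                           sigma=max(sigma_init, trace.sample_interval),
                           rss=float(resid @ resid), converged=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss, t, y,
                p0=[y0_init, a_init, t0_init, sigma_init],
                bounds=([-np.inf, 0.0, t[0] - duration, 1e-9],
                        [np.inf, np.inf, t[-1] + duration, duration]),
                xtol=1e-8, maxfev=1000 * 4,
            )
    except (RuntimeError, ValueError):
        return GaussianFit(y0=y0_init, A=a_init, t0=t0_init, sigma=sigma_init,
                           rss=float("nan"), converged=False)
    resid = y - _gauss(t, *popt)
    return GaussianFit(y0=float(popt[0]), A=float(popt[1]), t0=float(popt[2]),
                       sigma=float(popt[3]), rss=float(resid @ resid),
                       converged=True)


def _fwhm_sigma(t, y, y0, a) -> float:
    """Initial sigma from the full width at half of the amplitude estimate."""
    if a <= 0:
        return float(t[-1] - t[0]) / 4.0
    above = y >= y0 + 0.5 * a
    if not np.any(above):
        return float(t[-1] - t[0]) / 4.0
    idx = np.nonzero(above)[0]
    fwhm = float(t[idx[-1]] - t[idx[0]])
    dt = float(np.median(np.diff(t)))
    return max(fwhm, dt) / 2.355


def _crossing_time(t, y, i, level) -> float:
    """Time where y crosses ``level`` between samples i and i+1.

    A local cubic through up to four bracketing samples is solved for the
    crossing (sub-millisecond accuracy on smooth waveforms at 1.1 s
    sampling); falls back to linear interpolation when the local polynomial
    has no root inside the bracket.
    """
    span = float(t[i + 1] - t[i])
    if y[i + 1] == y[i]:
        linear = 0.0
    else:
        linear = float((level - y[i]) * span / (y[i + 1] - y[i]))
    lo, hi = max(0, i - 1), min(len(y), i + 3)
    if hi - lo >= 3:
        coef = np.polyfit(t[lo:hi] - t[i], y[lo:hi], deg=hi - lo - 1)
        coef[-1] -= level
        roots = np.roots(coef)
        real = roots[np.abs(roots.imag) < 1e-9].real
        inside = real[(real >= -1e-9) & (real <= span + 1e-9)]
        if inside.size:
            best = inside[np.argmin(np.abs(inside - linear))]
            return float(t[i] + min(max(best, 0.0), span))
    return float(t[i] + linear)


def _level_crossings(t, y, level):
    """All (time, direction) crossings of ``level``; direction +1 up, -1 down."""
    above = y >= level
    out = []
    for i in range(len(y) - 1):
        if above[i + 1] and not above[i]:
            out.append((_crossing_time(t, y, i, level), +1))
        elif above[i] and not above[i + 1]:
            out.append((_crossing_time(t, y, i, level), -1))
    return out


def _segments_above(t, y, level):
    """Contiguous (t_start, t_end, i_start, i_end) runs with y >= level."""
    above = np.asarray(y) >= level
    segs = []
    i = 0
    n = len(y)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            t_start = (t[i] if i == 0 else
                       _crossing_time(t, y, i - 1, level))
            t_end = (t[j] if j == n - 1 else
                     _crossing_time(t, y, j, level))
            segs.append((t_start, t_end, i, j))
            i = j + 1
        else:
            i += 1
    return segs


def _merge_segments(t, y, segs, floor_level):
    """Merge segments separated only by dips that stay above ``floor_level``.

    Noise chatter around the upper threshold fragments one sustained peak
    into many short runs; a genuine second transient dips at least to the
    half-amplitude level in between.
    """
    if len(segs) < 2:
        return segs
    merged = [segs[0]]
    for seg in segs[1:]:
        prev = merged[-1]
        gap_min = float(np.min(y[prev[3]:seg[2] + 1]))
        if gap_min >= floor_level:
            merged[-1] = (prev[0], seg[1], prev[2], seg[3])
        else:
            merged.append(seg)
    return merged


def extract_time_constants(
    trace: RatioTrace,
    fit: GaussianFit,
    lower: float = LOWER_FRACTION,
    upper: float = UPPER_FRACTION,
    on_fit: bool = False,
) -> TimeConstants:
    """Rise/dwell/fall time constants by 10%/90% amplitude thresholding.

    Thresholds are ``y0 + f*A`` from the fit; crossings are located on the
    measured ratio with linear interpolation (set ``on_fit=True`` to locate
    them on the fitted curve instead). Returns a flagged no-transient result —
    never an exception — when the fit failed or the amplitude is below the
    detection threshold (5x the robust pre-stimulus noise SD).
    """
    if not (0.0 < lower < upper < 1.0):
        raise ValueError("need 0 < lower < upper < 1")
    if not fit.converged:
        return TimeConstants(
            rise_time=float("nan"), dwell_time=float("nan"),
            fall_time=float("nan"), amplitude=0.0,
            crossings=(float("nan"),) * 4, detected=False,
            flags=("no_transient", "not_converged"))

    t = trace.time
    y = fit.predict(t) if on_fit else trace.ratio
    n_base = max(3, int(np.ceil(BASELINE_FRACTION * y.size)))
    noise_sd = _robust_sd(trace.ratio[:n_base])
    threshold = max(DETECTION_K * noise_sd, DETECTION_FLOOR)
    if fit.A < threshold:
        return NO_TRANSIENT

    lo_level = fit.y0 + lower * fit.A
    hi_level = fit.y0 + upper * fit.A
    mid_level = fit.y0 + 0.5 * fit.A
    hi_segs = _merge_segments(t, y, _segments_above(t, y, hi_level),
                              mid_level)
    if not hi_segs:
        return NO_TRANSIENT
    flags = []
    if len(hi_segs) > 1:
        flags.append("multi_peak")
        # time around the peak nearest the fitted centre
        hi_segs.sort(key=lambda s: abs(0.5 * (s[0] + s[1]) - fit.t0))
        hi_segs = [hi_segs[0]]
    hi_up, hi_down = hi_segs[0][0], hi_segs[0][1]

    # lower-level segment that contains the sustained peak; its ends are the
    # first 10% up-crossing into the transient and the last 10% down-crossing
    # out of it (noise blips far from the peak belong to other segments)
    lo_segs = _segments_above(t, y, lo_level)
    containing = [s for s in lo_segs if s[0] <= hi_up and s[1] >= hi_down]
    if containing:
        lo_up, lo_down = containing[0][0], containing[0][1]
    else:  # peak within the first/last samples: fall back to trace limits
        lo_up, lo_down = float(t[0]), float(t[-1])
    if lo_up <= t[0] or lo_down >= t[-1]:
        flags.append("edge_truncated")

    amplitude = float(np.max(trace.ratio) - fit.y0)
    return TimeConstants(
        rise_time=float(hi_up - lo_up),
        dwell_time=float(hi_down - hi_up),
        fall_time=float(lo_down - hi_down),
        amplitude=amplitude,
        crossings=(float(lo_up), float(hi_up), float(hi_down), float(lo_down)),
        detected=True,
        flags=tuple(flags),
    )


def detect_onset(trace: RatioTrace, fit: GaussianFit,
                 fraction: float = LOWER_FRACTION) -> OnsetResult:
    """Onset = first up-crossing of ``y0 + fraction*A`` on the measured ratio."""
    if not fit.converged:
        return OnsetResult(onset_time=float("nan"), detected=False)
    n_base = max(3, int(np.ceil(BASELINE_FRACTION * len(trace))))
    noise_sd = _robust_sd(trace.ratio[:n_base])
    if fit.A < max(DETECTION_K * noise_sd, DETECTION_FLOOR):
        return OnsetResult(onset_time=float("nan"), detected=False)
    level = fit.y0 + fraction * fit.A
    segs = _segments_above(trace.time, trace.ratio, level)
    peak_t = float(trace.time[np.argmax(trace.ratio)])
    containing = [s for s in segs if s[0] <= peak_t <= s[1]]
    if not containing:
        return OnsetResult(onset_time=float("nan"), detected=False)
    return OnsetResult(onset_time=float(containing[0][0]), detected=True)


def onset_lag(cytosolic: RatioTrace, nuclear: RatioTrace) -> float:
    """Nuclear onset minus cytosolic onset, in seconds.

    Raises ``ValueError`` when either onset is undetected (lag undefined).
    Negative lags (nuclear leading) are reported as-is.
    """
    lags = []
    for tr in (cytosolic, nuclear):
        fit = fit_gaussian(tr)
        onset = detect_onset(tr, fit)
        if not onset.detected:
            raise ValueError("onset undetected; lag undefined")
        lags.append(onset.onset_time)
    return float(lags[1] - lags[0])


@dataclass(frozen=True)
class FrontSpeed:
    """Wave-front speed (μm/s) with delta-method standard error."""

    speed: float
    speed_se: float
    slope: float
    slope_se: float
    n: int


def estimate_front_speed(onsets) -> FrontSpeed:
    """Front speed from (distance μm, onset s) pairs.

    Ordinary least squares of onset time on distance gives a slope in s/μm;
    speed = 1/slope, with SE propagated as ``slope_se / slope**2``. Raises
    ``ValueError`` for fewer than 2 distinct distances or a non-positive slope
    (no propagating front).
    """
    pairs = np.asarray(list(onsets), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected (distance, onset) pairs")
    d, onset = pairs[:, 0], pairs[:, 1]
    if np.unique(d).size < 2:
        raise ValueError("need at least 2 distinct distances")
    if d.size == 2:
        slope = float((onset[1] - onset[0]) / (d[1] - d[0]))
        slope_se = float("nan")
    else:
        fit = ols(d, onset)
        slope, slope_se = fit.slope, fit.slope_se
    if slope <= 0:
        raise ValueError("non-positive slope: no propagating front")
    return FrontSpeed(speed=1.0 / slope, speed_se=slope_se / slope ** 2,
                      slope=slope, slope_se=slope_se, n=int(d.size))


# ---------------------------------------------------------------------------
# table I/O and batch analysis


def read_trace_table(path) -> pd.DataFrame:
    """Read a trace table (tab-delimited or CSV) with a ``time_s`` column and
    ``<roi>_fluo4`` / ``<roi>_furared`` channel columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "time_s" not in df.columns:
        raise ValueError("trace table must contain a 'time_s' column")
    return df


def iter_roi_traces(df: pd.DataFrame):
    """Yield (roi_name, RatioTrace) for every ROI channel pair in a table."""
    time = df["time_s"].to_numpy(dtype=float)
    rois = sorted({c[:-len("_fluo4")] for c in df.columns
                   if c.endswith("_fluo4")})
    for roi in rois:
        red = f"{roi}_furared"
        if red not in df.columns:
            raise ValueError(f"missing FuraRed column for ROI {roi!r}")
        yield roi, RatioTrace(time=time,
                              fluo4=df[f"{roi}_fluo4"].to_numpy(dtype=float),
                              furared=df[red].to_numpy(dtype=float))


def analyze_traces(df: pd.DataFrame, lower: float = LOWER_FRACTION,
                   upper: float = UPPER_FRACTION) -> pd.DataFrame:
    """Per-ROI kinetics table (roi, y0, A, t0, sigma, amplitude, rise_s,
    dwell_s, fall_s, onset_s, flags) from a multi-ROI trace table."""
    rows = []
    for roi, trace in iter_roi_traces(df):
        fit = fit_gaussian(trace)
        tc = extract_time_constants(trace, fit, lower=lower, upper=upper)
        onset = detect_onset(trace, fit)
        rows.append({
            "roi": roi, "y0": fit.y0, "A": fit.A, "t0": fit.t0,
            "sigma": fit.sigma, "amplitude": tc.amplitude,
            "rise_s": tc.rise_time, "dwell_s": tc.dwell_time,
            "fall_s": tc.fall_time,
            "onset_s": onset.onset_time if onset.detected else float("nan"),
            "detected": tc.detected, "flags": ";".join(tc.flags),
        })
    return pd.DataFrame(rows)
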