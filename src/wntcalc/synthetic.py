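"""Synthetic imaging data with known ground truth.

Generates the three input kinds the analysis stages consume — ratiometric
calcium traces, two-channel nuclei images, and wound-width time courses — so
the full pipeline is testable without microscope data.

The calcium ratio waveform is modelled as a (possibly asymmetric) Gaussian
``r(t) = baseline + amplitude * exp(-(t-center)^2 / (2 sigma^2))`` with the
falling-limb width stretched by ``(1 + asymmetry)``. Channels are split so
the Fluo-4-like channel rises and the FuraRed-like channel falls
reciprocally while their ratio equals ``r(t)`` exactly in the noiseless
case:

    fluo4(t)   = F0 * sqrt(r(t) / baseline)
    furared(t) = (F0 / baseline) / sqrt(r(t) / baseline)

Channel noise is additive Gaussian with SD ``noise_sd * channel_base /
sqrt(2)``; for the default baseline ratio of 1 this puts an SD of
approximately ``noise_sd`` (in ratio units) on the ratio itself.

Ligand presets encode the study conditions: which ligands evoke a transient,
which dwell-time class each belongs to, and the shape of its dose-response
(first-order decay for negative cooperativity, Michaelis-Menten for Wnt5A
with half-maximal concentration 67 ng/ml, flat for Wnt7A).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cooperativity import ConcentrationSeries
from .kinetics import RatioTrace

__all__ = [
    "TransientParams",
    "LigandPreset",
    "DishLayout",
    "ColocImageParams",
    "WoundParams",
    "LIGAND_PRESETS",
    "DEFAULT_FRONT_SPEED",
    "simulate_trace",
    "simulate_dish",
    "simulate_thapsigargin_trace",
    "simulate_concentration_series",
    "simulate_coloc_images",
    "simulate_wound_series",
    "write_trace_table",
    "dump_presets",
]

PRESETS_VERSION = "1.0"

#: default calcium wave-front speed, μm/s (ligand diffusion across the dish)
DEFAULT_FRONT_SPEED = 23.3

#: mean photon counts of each channel at baseline
_CHANNEL_BASE = 100.0


@dataclass(frozen=True)
class TransientParams:
    """Ground-truth parameters of one Gaussian calcium transient.

    ``asymmetry >= 0`` stretches the falling limb: the width right of the
    centre is ``sigma * (1 + asymmetry)``.
    """

    baseline: float = 1.0          # ratio units
    amplitude: float = 1.0         # ratio units above baseline
    center_time: float = 200.0     # s
    sigma: float = 20.0            # s
    noise_sd: float = 0.0          # ratio units
    sample_interval: float = 1.1   # s (acquisition every 1.1 or 2.2 s)
    duration: float = 600.0        # s
    asymmetry: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if self.duration <= self.center_time:
            raise ValueError("duration must exceed center_time")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.asymmetry < 0:
            raise ValueError("asymmetry must be >= 0")
        if self.baseline <= 0:
            raise ValueError("baseline must be > 0")

    def curve(self, t) -> np.ndarray:
        """Noiseless ratio waveform at times ``t``."""
        t = np.asarray(t, dtype=float)
        sig = np.where(t <= self.center_time, self.sigma,
                       self.sigma * (1.0 + self.asymmetry))
        return self.baseline + self.amplitude * np.exp(
            -((t - self.center_time) ** 2) / (2.0 * sig ** 2))


@dataclass(frozen=True)
class LigandPreset:
    """Study conditions for one ligand: waveform, class, dose-response."""

    name: str
    transient: TransientParams | None
    kinetic_class: str                      # short | long | very_long | none
    dose_response: dict                     # {"mode": ..., parameters}

    def dose_response_curve(self, concentrations) -> np.ndarray:
        """Expected dwell time (s) at each concentration (ng/ml)."""
        c = np.asarray(concentrations, dtype=float)
        mode = self.dose_response["mode"]
        p = self.dose_response
        if mode == "negative_cooperative":
            return p["y0"] + p["A1"] * np.exp(-c / p["t1"])
        if mode == "michaelis_menten":
            return p["dt_max"] * c / (p["k_half"] + c)
        if mode == "flat":
            return np.full_like(c, p["value"])
        raise ValueError(f"unknown dose-response mode {mode!r}")


def _transient(sigma: float, amplitude: float) -> TransientParams:
    return TransientParams(baseline=1.0, amplitude=amplitude,
                           center_time=200.0, sigma=sigma)


# Noiseless dwell time of a symmetric Gaussian is 2*sigma*sqrt(2*ln(10/9))
# ≈ 0.918*sigma, so the widths below pin each preset inside its class
# interval (short < 15 s, 25 s < long <= 30 s, very long > 30 s).
LIGAND_PRESETS: dict[str, LigandPreset] = {
    "Wnt3A": LigandPreset(
        "Wnt3A", _transient(sigma=12.0, amplitude=1.2), "short",
        {"mode": "negative_cooperative", "y0": 8.0, "A1": 12.0, "t1": 120.0}),
    "Wnt5A": LigandPreset(
        "Wnt5A", _transient(sigma=14.0, amplitude=1.4), "short",
        {"mode": "michaelis_menten", "dt_max": 14.0, "k_half": 67.0}),
    "Wnt7A": LigandPreset(
        "Wnt7A", _transient(sigma=30.0, amplitude=1.1), "long",
        {"mode": "flat", "value": 27.5}),
    "Wnt10B": LigandPreset(
        "Wnt10B", _transient(sigma=31.0, amplitude=1.0), "long",
        {"mode": "negative_cooperative", "y0": 24.0, "A1": 15.0, "t1": 130.0}),
    "Wnt4": LigandPreset(
        "Wnt4", _transient(sigma=40.0, amplitude=1.5), "very_long",
        {"mode": "negative_cooperative", "y0": 32.0, "A1": 25.0, "t1": 150.0}),
    "Wnt9B": LigandPreset(
        "Wnt9B", _transient(sigma=38.0, amplitude=1.3), "very_long",
        {"mode": "negative_cooperative", "y0": 31.0, "A1": 20.0, "t1": 150.0}),
    "Wnt11": LigandPreset("Wnt11", None, "none",
                          {"mode": "flat", "value": 0.0}),
    "vehicle": LigandPreset("vehicle", None, "none",
                            {"mode": "flat", "value": 0.0}),
}


def dump_presets(path) -> None:
    """Write the versioned ligand-preset table as JSON."""
    payload = {"version": PRESETS_VERSION, "presets": {}}
    for name, p in LIGAND_PRESETS.items():
        payload["presets"][name] = {
            "transient": asdict(p.transient) if p.transient else None,
            "kinetic_class": p.kinetic_class,
            "dose_response": p.dose_response,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# trace simulation


def _split_channels(ratio: np.ndarray, baseline: float,
                    noise_sd: float, rng: np.random.Generator):
    """Split a ratio curve into rising Fluo-4 / falling FuraRed channels."""
    q = np.sqrt(ratio / baseline)
    fluo4 = _CHANNEL_BASE * q
    furared = (_CHANNEL_BASE / baseline) / q
    if noise_sd > 0:
        ch_sd = noise_sd * _CHANNEL_BASE / np.sqrt(2.0)
        fluo4 = fluo4 + rng.normal(0.0, ch_sd, size=ratio.size)
        furared = furared + rng.normal(0.0, ch_sd / baseline, size=ratio.size)
        furared = np.clip(furared, 1e-6 * _CHANNEL_BASE, None)
    return fluo4, furared


def simulate_trace(params: TransientParams, seed: int = 0) -> RatioTrace:
    """One ROI's two-channel trace; noiseless ratio equals ``params.curve``."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, params.duration + 0.5 * params.sample_interval,
                  params.sample_interval)
    ratio = params.curve(t)
    fluo4, furared = _split_channels(ratio, params.baseline,
                                     params.noise_sd, rng)
    return RatioTrace(time=t, fluo4=fluo4, furared=furared)


@dataclass(frozen=True)
class DishLayout:
    """ROI geometry for a wave-front simulation (distances in μm)."""

    roi_positions: tuple = ((0.0, 0.0), (233.0, 0.0))
    ligand_entry_point: tuple = (0.0, 0.0)
    front_speed: float = DEFAULT_FRONT_SPEED   # μm/s

    def __post_init__(self):
        if self.front_speed <= 0:
            raise ValueError("front_speed must be > 0")
        if len(set(self.distances())) < 2:
            raise ValueError("need >= 2 distinct ROI distances")

    def distances(self) -> tuple:
        ex, ey = self.ligand_entry_point
        return tuple(float(np.hypot(x - ex, y - ey))
                     for x, y in self.roi_positions)


def simulate_dish(layout: DishLayout, per_roi: TransientParams,
                  seed: int = 0) -> pd.DataFrame:
    """Multi-ROI trace table with onset delays ``distance / front_speed``.

    Columns: ``time_s`` then ``roi<i>_fluo4`` / ``roi<i>_furared`` per ROI —
    the tab-delimited dialect of the trace readers.
    """
    seeds = np.random.SeedSequence(seed).spawn(len(layout.roi_positions))
    t = np.arange(0.0, per_roi.duration + 0.5 * per_roi.sample_interval,
                  per_roi.sample_interval)
    out = {"time_s": t}
    for i, dist in enumerate(layout.distances(), start=1):
        delay = dist / layout.front_speed
        rng = np.random.default_rng(seeds[i - 1])
        shifted = TransientParams(
            baseline=per_roi.baseline, amplitude=per_roi.amplitude,
            center_time=per_roi.center_time + delay, sigma=per_roi.sigma,
            noise_sd=per_roi.noise_sd,
            sample_interval=per_roi.sample_interval,
            duration=per_roi.duration + delay, asymmetry=per_roi.asymmetry)
        ratio = shifted.curve(t)
        fluo4, furared = _split_channels(ratio, per_roi.baseline,
                                         per_roi.noise_sd, rng)
        out[f"roi{i}_fluo4"] = fluo4
        out[f"roi{i}_furared"] = furared
    return pd.DataFrame(out)


def simulate_thapsigargin_trace(
    seed: int = 0,
    stimulus_time: float = 60.0,
    wnt_time: float = 400.0,
    noise_sd: float = 0.0,
    sample_interval: float = 1.1,
    duration: float = 600.0,
) -> RatioTrace:
    """SERCA-blocked store-depletion fixture.

    Thapsigargin added at ``stimulus_time`` evokes a sharp transient that
    decays monotonically back to baseline well within 120 s of the stimulus;
    a Wnt ligand added later at ``wnt_time`` evokes nothing, because the
    intracellular stores are empty.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 0.5 * sample_interval, sample_interval)
    baseline, amplitude = 1.0, 0.8
    center = stimulus_time + 20.0
    sig_rise, sig_fall = 8.0, 18.0
    sig = np.where(t <= center, sig_rise, sig_fall)
    ratio = baseline + amplitude * np.exp(-((t - center) ** 2)
                                          / (2.0 * sig ** 2))
    ratio[t < stimulus_time] = baseline  # stores untouched before addition
    fluo4, furared = _split_channels(ratio, baseline, noise_sd, rng)
    return RatioTrace(time=t, fluo4=fluo4, furared=furared)


def write_trace_table(df: pd.DataFrame, path) -> None:
    """Write a trace table in the tab-delimited export dialect."""
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# concentration series


def simulate_concentration_series(
    preset: LigandPreset,
    concentrations,
    replicates: int = 10,
    noise_fraction: float = 0.05,
    seed: int = 0,
) -> ConcentrationSeries:
    """Replicate dwell times around the preset's dose-response curve.

    Noise is multiplicative log-normal: each observation is the curve value
    times ``exp(N(0, noise_fraction^2))``, keeping dwell times positive.
    """
    c = np.asarray(list(concentrations), dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if np.any(np.diff(c) < 0):
        raise ValueError("concentrations must be sorted ascending")
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    truth = preset.dose_response_curve(c)
    rng = np.random.default_rng(seed)
    obs = []
    for mu in truth:
        if noise_fraction > 0:
            vals = mu * np.exp(rng.normal(0.0, noise_fraction,
                                          size=replicates))
        else:
            vals = np.full(replicates, mu)
        obs.append(vals)
    return ConcentrationSeries(ligand=preset.name,
                               concentrations=tuple(c),
                               observations=tuple(tuple(v) for v in obs))


# ---------------------------------------------------------------------------
# colocalization images


@dataclass(frozen=True)
class ColocImageParams:
    """Layout of a synthetic two-channel (nuclear stain + immunolabel) field.

    ``nuclear_fraction`` is the fraction of each cell's immunolabel intensity
    placed inside the nucleus; ``None`` selects the group preset (control
    0.30, treated 0.75).
    """

    image_shape: tuple = (512, 512)
    n_cells: int = 30
    nucleus_radius: int = 10
    nuclear_fraction: float | None = None
    background_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.nuclear_fraction is not None and not (
                0.0 <= self.nuclear_fraction <= 1.0):
            raise ValueError("nuclear_fraction must lie in [0, 1]")
        if self.nucleus_radius < 2:
            raise ValueError("nucleus_radius must be >= 2")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")


# 0.25 is the geometric neutrality point at which the per-pixel immunolabel
# intensity is equal inside the nucleus and in the 2x-radius cytoplasm ring;
# the control preset sits just above it (weak positive correlation), the
# treated preset well above (strong nuclear enrichment).
GROUP_NUCLEAR_FRACTION = {"control": 0.30, "treated": 0.75}

#: per-cell total immunolabel intensity (arbitrary units)
_CELL_TOTAL = 20000.0
_DAPI_LEVEL = 150.0


def _place_nuclei(shape, n_cells, radius, rng, max_tries=20000):
    """Non-overlapping nucleus centres with room for a 2x cytoplasm ring."""
    margin = 2 * radius + 2
    min_d = 2 * (2 * radius + 2)    # whole-cell ROIs must not collide
    centres = []
    tries = 0
    while len(centres) < n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping nuclei "
                f"of radius {radius} in {shape}")
        cy = rng.integers(margin, shape[0] - margin)
        cx = rng.integers(margin, shape[1] - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_d ** 2
               for y, x in centres):
            centres.append((int(cy), int(cx)))
    return centres


def simulate_coloc_images(params: ColocImageParams, group: str = "control"):
    """Two-channel image stack plus labeled nucleus masks for one group.

    Returns ``(image, masks)`` where ``image`` has shape (2, H, W) — channel 0
    the nuclear counterstain (DAPI-like), channel 1 the immunolabel
    (Cy3-like) — and ``masks`` labels each nucleus 1..n_cells. Each cell's
    immunolabel total is split ``nuclear_fraction`` inside the nucleus disk
    and the remainder in a surrounding cytoplasm ring out to twice the
    nucleus radius.
    """
    if group not in GROUP_NUCLEAR_FRACTION:
        raise ValueError(f"unknown group {group!r}")
    frac = (params.nuclear_fraction if params.nuclear_fraction is not None
            else GROUP_NUCLEAR_FRACTION[group])
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    r = params.nucleus_radius
    centres = _place_nuclei((h, w), params.n_cells, r, rng)

    yy, xx = np.mgrid[0:h, 0:w]
    dapi = np.zeros((h, w))
    cy3 = np.zeros((h, w))
    masks = np.zeros((h, w), dtype=np.int32)
    for label, (cy, cx) in enumerate(centres, start=1):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nucleus = d2 <= r ** 2
        ring = (d2 > r ** 2) & (d2 <= (2 * r) ** 2)
        masks[nucleus] = label
        dapi[nucleus] = _DAPI_LEVEL
        n_nuc, n_ring = int(nucleus.sum()), int(ring.sum())
        cy3[nucleus] += frac * _CELL_TOTAL / n_nuc
        cy3[ring] += (1.0 - frac) * _CELL_TOTAL / n_ring
    if params.background_sd > 0:
        dapi = np.clip(dapi + rng.normal(0, params.background_sd, (h, w)), 0,
                       None)
        cy3 = np.clip(cy3 + rng.normal(0, params.background_sd, (h, w)), 0,
                      None)
    return np.stack([dapi, cy3]), masks


# ---------------------------------------------------------------------------
# wound closure


@dataclass(frozen=True)
class WoundParams:
    """Ground truth for a linearly closing scratch wound."""

    initial_width: float = 800.0   # μm
    closure_rate: float = 10.0     # μm/h, magnitude of the true slope
    sample_interval: float = 2.0   # h (imaging every 2 h)
    duration: float = 24.0         # h
    noise_sd: float = 0.0          # μm
    seed: int = 0

    def __post_init__(self):
        if self.initial_width <= 0:
            raise ValueError("initial_width must be > 0")
        if self.closure_rate < 0:
            raise ValueError("closure_rate must be >= 0")
        if self.sample_interval <= 0 or self.duration <= 0:
            raise ValueError("sampling must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_wound_series(params: WoundParams,
                          condition_rates: dict | None = None) -> pd.DataFrame:
    """Wound-width table, one condition per ``condition_rates`` entry.

    ``condition_rates`` maps condition label to closure rate (μm/h); when
    omitted a single condition named ``"control"`` with ``params.closure_rate``
    is produced. Width follows ``max(0, w0 - rate*t)`` plus additive noise,
    floored at zero.
    """
    if condition_rates is None:
        condition_rates = {"control": params.closure_rate}
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.duration + 0.5 * params.sample_interval,
                  params.sample_interval)
    frames = []
    for cond, rate in condition_rates.items():
        if rate < 0:
            raise ValueError("closure rate must be >= 0")
        width = np.maximum(0.0, params.initial_width - rate * t)
        if params.noise_sd > 0:
            width = np.maximum(
                0.0, width + rng.normal(0.0, params.noise_sd, size=t.size))
        frames.append(pd.DataFrame(
            {"condition": cond, "time_h": t, "width_um": width}))
    return pd.concat(frames, ignore_index=True)
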