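# Methods

## Waveform model and time constants

The calcium waveform of one ROI is the per-sample Fluo-4/FuraRed intensity
ratio. The analysis models one transient per trace as a single Gaussian

    r(t) = y0 + A · exp(−(t − t0)² / (2σ²))

fitted by nonlinear least squares (`scipy.optimize.curve_fit`,
Levenberg–Marquardt within bounds). Initialisation: `y0` = median of the
first 10% of samples, `A = max − y0`, `t0` = argmax, `σ` = FWHM/2.355 with
the FWHM measured at half of the amplitude estimate; bounds `A ≥ 0`,
`σ ∈ (0, duration]`; parameter tolerance 1e−8, at most 4000 function
evaluations. Optimizer failure is reported as `converged=False`, never
raised, so batch analyses degrade gracefully.

Time constants use two threshold levels `y0 + f·A`, `f = 0.10` and `0.90`.
The *fit* supplies the levels (robust baseline and amplitude); the
*measured* ratio supplies the crossing times. This split matters: a pure
Gaussian forces rise = fall, while real (and asymmetric synthetic)
waveforms have distinct rising and falling limbs, which only data-located
crossings preserve. A fit-located mode (`on_fit=True`) is available for
comparison.

- rise = first 90% up-crossing − first 10% up-crossing
- dwell = last 90% down-crossing − first 90% up-crossing
- fall = last 10% down-crossing − last 90% down-crossing
- amplitude = max(ratio) − y0 (the waveform peak above baseline; the
  fitted `A` is kept alongside for QC)

Crossing times are refined with a local cubic through up to four bracketing
samples (root of the local polynomial inside the bracket, falling back to
linear interpolation). At 1.1 s sampling this puts the noiseless crossing
error near 1e−5 s, against ~0.02 s for plain linear interpolation —
comfortably below the 1e−3 s agreement the closed-form Gaussian oracle
tests demand. For a symmetric Gaussian the closed forms are
`dwell = 2σ√(2 ln(10/9)) ≈ 0.918σ` and
`rise = fall = σ(√(2 ln 10) − √(2 ln(10/9))) ≈ 1.687σ`.

Segments above the 90% level separated only by dips that stay above the
50% level are merged before timing: threshold chatter from noise is not a
second peak, whereas a genuine second transient dips at least to
half-amplitude. If more than one merged segment remains the trace is
flagged `multi_peak` and timed around the segment nearest the fitted
centre. The 10%-level crossings are taken from the segment that contains
the sustained peak, so isolated baseline noise blips do not drag the onset
or fall edge outward.

**Detection threshold.** A trace is called "no transient" (flagged, never
an exception) when the fitted amplitude is below 5× the robust noise SD
(1.4826·MAD) of the pre-stimulus segment (first 10% of samples), with an
absolute floor of 1e−3 ratio units for noiseless traces. This is the
criterion by which non-responding conditions (Wnt11, vehicle,
thapsigargin-pretreated) are reported.

**Known bias.** Locating extreme crossings on noisy data biases dwell
outward by roughly the noise SD divided by the waveform slope at the 90%
level — a few seconds at ratio noise SD 0.02 for wide transients. This is
inherent to amplitude thresholding on measured data; consequently a preset
lying within ~2 s of a class boundary can drift one class at realistic
noise. Class-boundary checks are therefore defined on noiseless waveforms,
and analyses of noisy data should average dwell across ROIs.

## Onsets, lag and front speed

Onset is the start of the 10%-level segment containing the peak. The
cytosol→nucleus lag is the difference of nuclear and cytosolic onsets
(negative if the nucleus leads; undefined — an error — if either onset is
undetected). Front speed comes from OLS regression of onset time on ROI
distance from the ligand entry point; speed = 1/slope with the delta-method
standard error `SE(speed) = SE(slope)/slope²`. A non-positive slope is a
non-propagating front and is rejected.

## Classification

Dwell-time classes: short (DT < 15 s), long (25 < DT ≤ 30 s), very long
(DT > 30 s). Because the published bounds leave 15–25 s unassigned and make
">30" a subset of ">25", the mapping applies very-long before long and
labels the 15–25 s gap `intermediate`, making classification total and
deterministic. Pairwise ligand comparisons use the two-sided Mann-Whitney
U test, uncorrected by default (each ligand against a chosen reference,
then remaining pairs in descending median order); Bonferroni or Holm
adjustment is available by flag.

## Statistics

`mann_whitney_u` delegates to `scipy.stats.mannwhitneyu`: exact enumeration
when the combined sample size is ≤ 12 with no ties, otherwise the normal
approximation with mid-rank tie correction and continuity correction. When
U equals its null mean the two-sided p is set to exactly 1 (symmetry of the
null), which the continuity-corrected approximation otherwise understates.
The exact path is cross-checked in the tests against brute-force
enumeration of all rank arrangements. Simple regression (`ols`) wraps
`scipy.stats.linregress` and is cross-checked against the normal
equations.

## Dose-response diagnosis

Fits run on per-concentration means (replicate-level fitting is an
option): first-order decay `y0 + A1·e^(−x/t1)` with `k = 1/t1` (three
parameters, needs ≥ 3 distinct concentrations) and Michaelis–Menten
`DTmax·C/(K½+C)`. Near-constant data make `A1 ≈ 0` with `t1`
unidentifiable; such fits are flagged rather than raised.

Diagnosis compares adjacent concentration pairs with two-sided
Mann-Whitney at α = 0.05, uncorrected: no significant pair →
`flat/indeterminate`; significant decrease(s) and no increase →
`negative_cooperative`; significant increase(s) and no decrease →
`michaelis_menten`; mixed directions → `flat/indeterminate`. Both fits are
attached, the lower-RSS one named as support. Because ranks drive the
tests, the diagnosis is invariant to replicate order and to rescaling all
observations by a positive constant. Note that with two adjacent pairs per
ligand at α = 0.05 a genuinely flat ligand is falsely called directional in
roughly one run in ten — the cost of mirroring uncorrected pairwise
testing.

## Colocalization

Per-cell Pearson correlation between immunolabel and nuclear-stain pixels,
computed plainly over ROI pixels — no intensity thresholding, no Costes
randomization — with an optional background-subtraction flag (median
outside all cells). Default ROI is the whole cell: each nucleus mask
expanded to about twice its equivalent radius
(`skimage.segmentation.expand_labels`, contested pixels to the nearest
nucleus); nucleus-only mode is available. Z-stacks are max-projected per
channel. Constant channels on an ROI yield a flagged NaN. Groups are
compared cell-wise with the two-sided Mann-Whitney test. Absolute r values
depend on unknowable acquisition settings; only the treated-vs-control
ordering and its significance are meaningful.

## Wound closure

Closure rate = −slope of OLS width-on-time. Slope equality between two
conditions uses the extra-sum-of-squares F-test (full model: per-condition
slope and intercept; reduced: common slope, separate intercepts;
F(1, n_a+n_b−4)), the standard slope-equality comparison. With both RSS
exactly zero (noiseless lines of different slope) F is infinite and p is
reported as 0. Widths are not censored during fitting; the generator
defaults avoid zero-touching.

## Synthetic data: what it emulates, and what it does not

`synthetic` generates the three input kinds with exact ground truth.

**Traces.** The ratio is the (optionally asymmetric) Gaussian above; the
falling-limb σ is stretched by (1 + asymmetry). Channels split as
`fluo4 = F0·√(r/r0)`, `furared = (F0/r0)/√(r/r0)` (F0 = 100 counts,
r0 = baseline ratio), so Fluo-4 rises while FuraRed falls reciprocally and
the noiseless ratio equals the designed curve exactly. Channel noise is
additive Gaussian with SD `noise_sd·F0/√2` per channel, giving ratio noise
SD ≈ `noise_sd` at the default baseline ratio of 1. Default sampling is
one frame per 1.1 s for 600 s (acquisition-rate presets 1.1/2.2 s).

**Ligand presets** fix the study conditions. Transient widths are chosen so
the noiseless dwell `0.918σ` sits inside each class interval: Wnt3A σ=12,
Wnt5A σ=14 (short); Wnt7A σ=30, Wnt10B σ=31 (long); Wnt4 σ=40, Wnt9B σ=38
(very long); Wnt11 and vehicle produce no transient. Dose-response modes:
Wnt3A/4/9B/10B negative-cooperative first-order decay (fixture `y0`, `A1`,
`t1` per ligand, e.g. Wnt9B 31 + 20·e^(−C/150)); Wnt5A Michaelis–Menten
with DTmax = 14 s and K½ = 67 ng/ml; Wnt7A flat at 27.5 s. Concentration
series add multiplicative log-normal noise (σ_log = noise_fraction),
keeping dwell times positive. The versioned preset table can be exported
with `dump_presets`.

**Dish.** ROI onset delays are exactly distance/front_speed (default front
speed 23.3 µm/s, the measured ligand spreading speed in a static dish).

**Thapsigargin fixture.** Baseline 1.0 before the stimulus; a sharp
transient (amplitude 0.8, rise σ 8 s, fall σ 18 s, peak 20 s after
addition) that re-enters the 5%-of-baseline band ~63 s after the stimulus
and stays (the return criterion requires ≥ 3 consecutive in-band samples);
a later Wnt addition produces nothing, emulating store depletion.

**Colocalization images.** Non-overlapping disk nuclei (radius 10 px,
centres ≥ 2 cell-diameters apart) on a 512² field; the DAPI channel marks
nuclei, and each cell's immunolabel total is split `nuclear_fraction`
inside the nucleus and the rest in a ring out to 2× the radius. At the 2×
ring geometry the per-pixel intensities equalize at fraction 0.25; the
control preset (0.30) therefore yields weakly positive per-cell r and the
treated preset (0.75) strongly positive r, giving the designed group
ordering by construction. Gaussian background (SD 2) is added and clipped
at zero.

**Wounds.** `width(t) = max(0, w0 − rate·t)` plus additive Gaussian noise,
floored at zero; sampled every 2 h.

All generators are bit-reproducible from one explicit seed per call
(`numpy.random.default_rng`; multi-ROI and pipeline stages spawn child
seeds via `SeedSequence`).

**What passing tests do not show.** The generator omits photobleaching,
dye saturation, cell-to-cell waveform heterogeneity beyond the onset
shift, oscillatory calcium responses, segmentation error (masks are exact)
and 3-D effects. Results on real data therefore inherit only the
correctness of the measurement chain, not these robustness properties.

## Problem sizes

Default analyses are desk-scale: 546-sample traces, 8-ROI dishes, 3–4
concentration × 10 replicate series, 30-cell image groups on a 512² field,
and 200-run recovery / 2000-run null-calibration simulations — each stage
completes in seconds on one core.

## Limitations

- One transient per trace; oscillations and spike trains are out of scope.
- Dwell/rise/fall carry the outward noise bias discussed above.
- Absolute Pearson coefficients are acquisition-dependent; only ordering
  and significance transfer to real data.
- The exact Mann-Whitney path requires tie-free data; ties switch to the
  tie-corrected normal approximation even at small n.
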