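# wntcalc

Quantitative analysis of Wnt-evoked intracellular calcium transients and
β-catenin nuclear translocation, for live-cell ratiometric imaging
(Fluo-4 / FuraRed) of cultured cells.

Wnt ligands signal through β-catenin-dependent ("canonical") and
calcium-dependent ("non-canonical") branches. In ratiometric imaging, a Wnt
application evokes a transient rise of the Fluo-4/FuraRed intensity ratio in
each cell; the shape of that waveform — in particular how long the signal is
sustained at its peak — distinguishes ligands, and the calcium release is
followed by β-catenin translocation into the nucleus. `wntcalc` implements
the full quantitative chain for such experiments:

1. **Waveform kinetics.** Each ROI's ratio trace is fitted with a single
   Gaussian `y0 + A·exp(−(t−t0)²/2σ²)`. The fitted baseline and amplitude
   define 10% and 90% threshold levels `y0 + f·A`, whose crossing times —
   located on the measured ratio — give the *rise* time (10%→90%
   up-crossings), *dwell* time (time spent above the 90% level) and *fall*
   time (90%→10% down-crossings). Amplitude is reported as
   `max(ratio) − y0`.
2. **Classification.** Ligands are assigned a kinetic class from dwell time
   (DT): short (DT < 15 s), long (25 < DT ≤ 30 s), very long (DT > 30 s);
   pairwise ligand comparisons use the Mann-Whitney U test.
3. **Cooperativity.** Dwell time vs ligand concentration is fitted with a
   first-order decay `y0 + A1·e^(−x/t1)` (rate constant `k = 1/t1`;
   decreasing response = negative cooperativity) and with a Michaelis–Menten
   curve `DTmax·C/(K½ + C)`; adjacent-concentration Mann-Whitney tests
   diagnose which regime a ligand follows.
4. **Wave front and onset lag.** Onset times of ROIs at increasing distance
   from the ligand entry point are regressed on distance to estimate the
   front speed (µm/s); the cytosol→nucleus onset lag is the difference of
   the two 10%-level onsets.
5. **Colocalization.** Nuclear translocation is quantified as the per-cell
   Pearson correlation between the immunolabel (Cy3) and nuclear stain
   (DAPI) channels over whole-cell ROIs, compared across groups by
   Mann-Whitney.
6. **Motility.** Scratch-wound closure rates from linear regression of
   wound width on time, with an extra-sum-of-squares F-test for slope
   equality between conditions.

A synthetic-data module generates all three input kinds (trace tables,
two-channel nuclei images, wound-width tables) with known ground truth, so
every stage is testable without microscope data.

## Worked example

```python
import wntcalc as w

preset = w.LIGAND_PRESETS["Wnt9B"]
trace = w.simulate_trace(preset.transient, seed=0)      # noiseless waveform
fit = w.fit_gaussian(trace)
tc = w.extract_time_constants(trace, fit)
print(f"baseline={fit.y0:.3f} amplitude={fit.A:.3f} "
      f"centre={fit.t0:.1f}s sigma={fit.sigma:.1f}s")
print(f"rise={tc.rise_time:.1f}s dwell={tc.dwell_time:.1f}s "
      f"fall={tc.fall_time:.1f}s -> {w.classify_dwell(tc.dwell_time)}")

series = w.simulate_concentration_series(
    preset, [30, 100, 300], replicates=10, noise_fraction=0.05, seed=1)
diag = w.diagnose(series)
print(f"{series.ligand}: {diag.mode} (k = {diag.decay_fit.k:.4f} per ng/ml)")
```

prints

```
baseline=1.000 amplitude=1.300 centre=200.0s sigma=38.0s
rise=64.1s dwell=34.9s fall=64.1s -> very_long
Wnt9B: negative_cooperative (k = 0.0077 per ng/ml)
```

The fitted parameters recover the generating preset exactly (noiseless
trace); the 34.9 s dwell places Wnt9B in the very-long class, and across a
30–300 ng/ml series its dwell time *decreases* with concentration —
diagnosed as negative cooperativity with the fitted first-order rate
constant shown. Running the same series for the Wnt5A preset instead yields
`michaelis_menten` with `K½` near 67 ng/ml.

The same stages are available from the shell:

```sh
wntcalc simulate --ligand Wnt9B --seed 5 --noise-sd 0 --out traces.tsv
wntcalc kinetics --traces traces.tsv --out kinetics.csv
wntcalc classify --kinetics kinetics.csv --out classes.csv
wntcalc run-all --seed 0 --out study_out     # full synthetic study
```

Trace tables are tab-delimited (`time_s`, then `<roi>_fluo4`,
`<roi>_furared` per ROI); images are multi-page TIFF plus a labeled-mask
TIFF.

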