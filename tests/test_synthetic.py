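"""Ground-truth properties of the synthetic-data generators."""

import numpy as np
import pytest

from wntcalc import (LIGAND_PRESETS, ColocImageParams, DishLayout,
                     TransientParams, WoundParams, simulate_coloc_images,
                     simulate_concentration_series, simulate_dish,
                     simulate_thapsigargin_trace, simulate_trace,
                     simulate_wound_series)
from wntcalc.colocalization import per_cell_coloc
from wntcalc.synthetic import write_trace_table


class TestTransientTraces:
    def test_zero_amplitude_gives_constant_ratio(self):
        tr = simulate_trace(TransientParams(baseline=1.0, amplitude=0.0),
                            seed=0)
        assert np.allclose(tr.ratio, 1.0, atol=1e-12)

    def test_noiseless_peak_equals_baseline_plus_amplitude(self):
        params = TransientParams(baseline=1.0, amplitude=1.5,
                                 center_time=200.0, sigma=20.0,
                                 sample_interval=2.0)
        tr = simulate_trace(params, seed=0)
        i200 = np.argmin(np.abs(tr.time - 200.0))
        assert tr.time[i200] == pytest.approx(200.0, abs=1e-9)
        assert tr.ratio[i200] == pytest.approx(2.5, abs=1e-12)

    def test_noiseless_ratio_is_exactly_the_generating_curve(self):
        params = TransientParams(baseline=1.2, amplitude=0.9,
                                 center_time=150.0, sigma=25.0,
                                 asymmetry=0.5)
        tr = simulate_trace(params, seed=0)
        assert np.max(np.abs(tr.ratio - params.curve(tr.time))) < 1e-12

    def test_symmetric_trace_mirrors_about_centre(self):
        params = TransientParams(baseline=1.0, amplitude=1.5,
                                 center_time=200.0, sigma=20.0,
                                 sample_interval=1.0, duration=400.0)
        tr = simulate_trace(params, seed=0)
        idx = np.argmin(np.abs(tr.time - 200.0))
        for delta in (10, 37, 90):
            assert tr.ratio[idx - delta] == pytest.approx(
                tr.ratio[idx + delta], abs=1e-12)

    def test_fluo4_rises_while_furared_falls(self):
        tr = simulate_trace(TransientParams(amplitude=1.0), seed=0)
        peak = np.argmax(tr.ratio)
        assert tr.fluo4[peak] > tr.fluo4[0]
        assert tr.furared[peak] < tr.furared[0]

    def test_bit_reproducible_given_seed(self):
        params = TransientParams(amplitude=1.0, noise_sd=0.05)
        a = simulate_trace(params, seed=123)
        b = simulate_trace(params, seed=123)
        assert np.array_equal(a.fluo4, b.fluo4)
        assert np.array_equal(a.furared, b.furared)

    @pytest.mark.parametrize("bad", [
        dict(amplitude=-1.0), dict(sigma=0.0), dict(sample_interval=0.0),
        dict(noise_sd=-0.1), dict(duration=100.0, center_time=200.0),
        dict(asymmetry=-0.5),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            TransientParams(**bad)


class TestDish:
    def test_delay_is_distance_over_speed(self):
        layout = DishLayout(roi_positions=((0.0, 0.0), (233.0, 0.0)),
                            front_speed=23.3)
        params = TransientParams(amplitude=1.0, center_time=100.0,
                                 duration=400.0)
        df = simulate_dish(layout, params, seed=0)
        t = df["time_s"].to_numpy()
        t1 = t[np.argmax(df["roi1_fluo4"].to_numpy())]
        t2 = t[np.argmax(df["roi2_fluo4"].to_numpy())]
        assert t2 - t1 == pytest.approx(10.0, abs=params.sample_interval)

    def test_roi_at_entry_point_is_unshifted(self):
        layout = DishLayout(roi_positions=((0.0, 0.0), (100.0, 0.0)))
        params = TransientParams(amplitude=1.0, center_time=100.0,
                                 duration=400.0, sample_interval=0.5)
        df = simulate_dish(layout, params, seed=0)
        t = df["time_s"].to_numpy()
        assert t[np.argmax(df["roi1_fluo4"].to_numpy())] == pytest.approx(
            100.0, abs=0.5)

    def test_doubling_speed_halves_delays(self):
        params = TransientParams(amplitude=1.0, center_time=100.0,
                                 duration=400.0, sample_interval=0.5)
        delays = []
        for speed in (10.0, 20.0):
            layout = DishLayout(roi_positions=((0.0, 0.0), (200.0, 0.0)),
                                front_speed=speed)
            df = simulate_dish(layout, params, seed=0)
            t = df["time_s"].to_numpy()
            delays.append(t[np.argmax(df["roi2_fluo4"])]
                          - t[np.argmax(df["roi1_fluo4"])])
        assert delays[0] == pytest.approx(2.0 * delays[1], abs=1.0)

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError):
            DishLayout(front_speed=-1.0)
        with pytest.raises(ValueError):
            DishLayout(roi_positions=((5.0, 0.0), (0.0, 5.0)))  # equidistant

    def test_trace_table_dialect_round_trips(self, tmp_path):
        from wntcalc.kinetics import read_trace_table
        layout = DishLayout(roi_positions=((0.0, 0.0), (100.0, 0.0)))
        df = simulate_dish(layout, TransientParams(amplitude=1.0), seed=0)
        path = tmp_path / "traces.tsv"
        write_trace_table(df, path)
        assert "\t" in path.read_text().splitlines()[0]
        back = read_trace_table(path)
        assert list(back.columns) == list(df.columns)
        assert np.allclose(back.to_numpy(), df.to_numpy())


class TestThapsigargin:
    def test_pre_stimulus_baseline_constant(self):
        tr = simulate_thapsigargin_trace(seed=0, stimulus_time=60.0)
        assert np.allclose(tr.ratio[tr.time < 60.0], 1.0, atol=1e-12)

    def test_returns_to_baseline_within_120s(self):
        tr = simulate_thapsigargin_trace(seed=0, stimulus_time=60.0)
        after = tr.time >= 60.0
        t, r = tr.time[after], tr.ratio[after]
        within = np.abs(r - 1.0) <= 0.05
        returned = None
        for i in range(np.argmax(r), len(r) - 2):
            if within[i] and within[i + 1] and within[i + 2]:
                returned = t[i]
                break
        assert returned is not None
        assert returned - 60.0 <= 120.0

    def test_decay_is_monotonic_after_peak(self):
        tr = simulate_thapsigargin_trace(seed=0)
        peak = np.argmax(tr.ratio)
        assert np.all(np.diff(tr.ratio[peak:]) <= 1e-12)

    def test_post_thapsigargin_ligand_evokes_nothing(self):
        from wntcalc import RatioTrace, extract_time_constants, fit_gaussian
        tr = simulate_thapsigargin_trace(seed=0, stimulus_time=60.0,
                                         wnt_time=400.0)
        seg = tr.time >= 300.0
        segment = RatioTrace(time=tr.time[seg], fluo4=tr.fluo4[seg],
                             furared=tr.furared[seg])
        fit = fit_gaussian(segment)
        tc = extract_time_constants(segment, fit)
        assert not tc.detected
        assert "no_transient" in tc.flags


class TestConcentrationSeries:
    def test_michaelis_menten_half_maximum_at_k_half(self):
        preset = LIGAND_PRESETS["Wnt5A"]
        series = simulate_concentration_series(
            preset, [30.0, 67.0, 300.0], replicates=3, noise_fraction=0.0,
            seed=0)
        dt_max = preset.dose_response["dt_max"]
        assert np.mean(series.observations[1]) == pytest.approx(dt_max / 2.0)

    def test_negative_cooperative_means_strictly_decrease(self):
        series = simulate_concentration_series(
            LIGAND_PRESETS["Wnt9B"], [30.0, 100.0, 300.0, 600.0],
            replicates=3, noise_fraction=0.0, seed=0)
        assert np.all(np.diff(series.means()) < 0)

    def test_flat_preset_constant(self):
        series = simulate_concentration_series(
            LIGAND_PRESETS["Wnt7A"], [30.0, 100.0, 300.0], replicates=3,
            noise_fraction=0.0, seed=0)
        assert np.ptp(series.means()) == 0.0

    def test_noiseless_means_lie_on_the_curve(self, responding_presets):
        conc = [30.0, 100.0, 300.0]
        for preset in responding_presets.values():
            series = simulate_concentration_series(
                preset, conc, replicates=2, noise_fraction=0.0, seed=0)
            assert np.allclose(series.means(),
                               preset.dose_response_curve(conc))

    def test_unsorted_concentrations_rejected(self):
        with pytest.raises(ValueError):
            simulate_concentration_series(LIGAND_PRESETS["Wnt5A"],
                                          [300.0, 30.0], replicates=3)


def test_preset_file_dump_covers_all_ligands(tmp_path):
    import json

    from wntcalc.synthetic import dump_presets
    path = tmp_path / "presets.json"
    dump_presets(path)
    payload = json.loads(path.read_text())
    assert payload["version"]
    assert set(payload["presets"]) == set(LIGAND_PRESETS)
    assert payload["presets"]["Wnt5A"]["dose_response"]["k_half"] == 67.0
    assert payload["presets"]["Wnt11"]["transient"] is None


class TestColocImages:
    def test_full_nuclear_fraction_puts_all_label_in_nuclei(self):
        img, masks = simulate_coloc_images(
            ColocImageParams(n_cells=5, nuclear_fraction=1.0,
                             background_sd=0.0, seed=1), "control")
        assert img[1][masks == 0].sum() == 0.0
        assert img[1][masks > 0].sum() > 0.0

    def test_zero_nuclear_fraction_empties_nuclei(self):
        img, masks = simulate_coloc_images(
            ColocImageParams(n_cells=5, nuclear_fraction=0.0,
                             background_sd=0.0, seed=1), "control")
        assert img[1][masks > 0].sum() == 0.0

    def test_nuclei_do_not_overlap_and_count_matches(self):
        img, masks = simulate_coloc_images(
            ColocImageParams(n_cells=20, seed=3), "control")
        labels = np.unique(masks)
        assert labels[0] == 0 and labels.size == 21
        # each labeled disk has the full disk area: no clipping/overlap
        areas = [(masks == l).sum() for l in labels[1:]]
        assert np.ptp(areas) == 0

    def test_treated_preset_more_nuclear_than_control(self):
        ci, cm = simulate_coloc_images(ColocImageParams(n_cells=15, seed=5),
                                       "control")
        ti, tm = simulate_coloc_images(ColocImageParams(n_cells=15, seed=6),
                                       "treated")
        rc = np.mean([r.pearson_r
                      for r in per_cell_coloc(ci, cm, "control")])
        rt = np.mean([r.pearson_r
                      for r in per_cell_coloc(ti, tm, "treated")])
        assert rt > rc

    def test_impossible_layout_raises(self):
        with pytest.raises(RuntimeError):
            simulate_coloc_images(
                ColocImageParams(image_shape=(64, 64), n_cells=50,
                                 nucleus_radius=10, seed=0), "control")


class TestWounds:
    def test_noiseless_width_decreases_linearly(self):
        params = WoundParams(initial_width=800.0, closure_rate=10.0,
                             sample_interval=2.0, duration=10.0,
                             noise_sd=0.0)
        table = simulate_wound_series(params)
        widths = table["width_um"].to_numpy()
        assert np.allclose(np.diff(widths), -20.0)

    def test_zero_rate_constant_width(self):
        table = simulate_wound_series(WoundParams(closure_rate=0.0))
        assert np.ptp(table["width_um"].to_numpy()) == 0.0

    def test_two_conditions_slopes_scale(self):
        from wntcalc import WoundSeries, fit_closure_rate
        table = simulate_wound_series(
            WoundParams(noise_sd=0.0, duration=12.0),
            condition_rates={"fast": 10.0, "slow": 5.0})
        rates = {}
        for cond, g in table.groupby("condition"):
            series = WoundSeries(cond, tuple(g["time_h"]),
                                 tuple(g["width_um"]))
            rates[cond] = fit_closure_rate(series).rate
        assert rates["fast"] == pytest.approx(2.0 * rates["slow"])

    def test_width_floored_at_zero(self):
        table = simulate_wound_series(
            WoundParams(initial_width=50.0, closure_rate=10.0,
                        duration=24.0, noise_sd=0.0))
        assert table["width_um"].min() == 0.0
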