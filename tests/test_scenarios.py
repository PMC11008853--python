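"""Tests of the synthetic chip-experiment registry, noise, device
arithmetic and exclusion filtering."""

import numpy as np
import pandas as pd
import pytest

from dermakin import (
    DeviceConstants,
    ExclusionCriteria,
    FitConfig,
    NoiseModel,
    apply_exclusion_criteria,
    concentration_to_cumulative_mass,
    default_exclusion_criteria,
    generate_scenario,
    get_scenario,
    multistart_fit,
    scenario_defaults,
    summarize_dataset,
)


class TestRegistry:
    def test_thirteen_unique_scenarios(self):
        scs = scenario_defaults()
        assert len(scs) == 13
        assert len({s.id for s in scs}) == 13

    def test_endpoints_inside_published_windows(self):
        for sc in scenario_defaults():
            if sc.qc_window is not None:
                lo, hi = sc.qc_window
                assert lo <= sc.noise_free_endpoint <= hi, sc.id

    def test_caffeine_rt_window(self):
        ep = get_scenario("caffeine-rt-6h").noise_free_endpoint
        assert 20.0 <= ep <= 50.0

    def test_disease_fold_changes(self):
        """Psoriatic skin passes > 4x its control at 24 h and > 3.5x at
        96 h; the allergic ear passes 1.3x its control."""
        ep = {s.id: s.noise_free_endpoint for s in scenario_defaults()}
        assert ep["psoriasis-imq-24h"] / ep["psoriasis-control-24h"] > 4.0
        assert ep["psoriasis-imq-96h"] / ep["psoriasis-control-96h"] > 3.5
        assert ep["acd-tncb"] / ep["acd-control"] == pytest.approx(1.3, rel=1e-9)

    def test_temperature_increases_penetration(self):
        assert (
            get_scenario("caffeine-32c-6h").noise_free_endpoint
            > get_scenario("caffeine-rt-6h").noise_free_endpoint
        )

    def test_sampling_grids_match_device_schedule(self):
        sc = get_scenario("caffeine-rt-6h")
        assert sc.n_samples == 12 and sc.times[0] == 0 and sc.times[-1] == 6
        acd = get_scenario("acd-control")
        assert acd.interval_min == 15 and acd.times.size == 21

    def test_unknown_scenario(self):
        with pytest.raises(KeyError):
            get_scenario("nope")

    def test_diclofenac_window_flagged_inconsistent(self):
        assert "window_inconsistent" in get_scenario("diclofenac-6h").flags


class TestGeneration:
    def test_zero_noise_reproduces_model_curve(self):
        sc = get_scenario("caffeine-rt-6h")
        reps, truth = generate_scenario(sc, noise=NoiseModel(0.0, 0.0), seed=1)
        y0 = sc.simulate().values
        assert truth == sc.params
        for r in reps:
            np.testing.assert_array_equal(r.values, y0)

    def test_deterministic_given_seed(self):
        a, _ = generate_scenario("acd-tncb", seed=42)
        b, _ = generate_scenario("acd-tncb", seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_replicates_nonnegative_and_monotone(self):
        reps, _ = generate_scenario("caffeine-32c-6h", seed=3)
        for r in reps:
            assert np.all(r.values >= 0)
            assert np.all(np.diff(r.values) >= 0)

    def test_replicate_mean_tracks_noise_free_curve(self):
        """Law of large numbers: the mean of many replicates stays within
        three standard errors of the model curve."""
        sc = get_scenario("caffeine-rt-6h")
        reps, _ = generate_scenario(sc, n_replicates=50, seed=11)
        values = np.vstack([r.values for r in reps])
        mean = values.mean(axis=0)
        sem = values.std(axis=0, ddof=1) / np.sqrt(values.shape[0])
        y0 = sc.simulate().values
        mask = sem > 0
        assert np.all(np.abs(mean[mask] - y0[mask]) < 3 * sem[mask] + 1e-12)

    def test_noise_free_roundtrip_recovers_scenario_truth(self):
        """Calibration on a scenario's own noise-free curve returns the
        shipped ground-truth rates (identifiable regime by design)."""
        for sid in ("caffeine-rt-6h", "piroxicam-6h", "psoriasis-imq-24h",
                    "acd-control"):
            sc = get_scenario(sid)
            data = sc.simulate()
            fit = multistart_fit(data, FitConfig(n_starts=6, seed=2))
            rel = np.max(
                np.abs(fit.params.as_array() - sc.params.as_array())
                / sc.params.as_array()
            )
            assert rel < 1e-3, sid

    def test_invalid_replicates(self):
        with pytest.raises(ValueError):
            generate_scenario("acd-control", n_replicates=0)


class TestDeviceArithmetic:
    def test_constant_concentration_conversion(self):
        """1 μg/mL sampled every 30 min at 4 μL/min: 0.12 μg per sample,
        0.24 μg/cm² cumulative increments over the 0.5 cm² window."""
        obs = concentration_to_cumulative_mass(np.ones(4), 30.0)
        np.testing.assert_allclose(np.diff(obs.values, prepend=0), 0.24)
        np.testing.assert_allclose(obs.times, [0.5, 1.0, 1.5, 2.0])

    def test_zero_concentrations(self):
        obs = concentration_to_cumulative_mass(np.zeros(5), 15.0)
        np.testing.assert_array_equal(obs.values, 0.0)

    def test_output_nondecreasing(self, rng):
        obs = concentration_to_cumulative_mass(rng.uniform(0, 5, 20), 15.0)
        assert np.all(np.diff(obs.values) >= 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            concentration_to_cumulative_mass([1.0, -0.1], 30.0)

    def test_device_constants(self):
        d = DeviceConstants()
        assert d.flow_rate_ul_min == 4.0 and d.diffusion_area_cm2 == 0.5


class TestExclusion:
    def test_mouse_body_weight_example(self):
        df = pd.DataFrame({"mouse_body_weight_g": [19.0, 25.0, 33.0]})
        crit = default_exclusion_criteria().subset(["mouse_body_weight_g"])
        kept, report = apply_exclusion_criteria(df, crit)
        assert kept["mouse_body_weight_g"].tolist() == [25.0]
        assert len(report) == 2
        assert set(report["violated_bound"]) == {20.0, 32.0}

    def test_caffeine_endpoint_example(self):
        df = pd.DataFrame({"caffeine_6h_rt_ug_cm2": [18.0, 35.0, 55.0]})
        crit = default_exclusion_criteria().subset(["caffeine_6h_rt_ug_cm2"])
        kept, report = apply_exclusion_criteria(df, crit)
        assert kept["caffeine_6h_rt_ug_cm2"].tolist() == [35.0]
        assert sorted(report["violated_bound"]) == [20.0, 50.0]

    def test_bounds_inclusive(self):
        df = pd.DataFrame({"mouse_body_weight_g": [20.0, 32.0]})
        crit = default_exclusion_criteria().subset(["mouse_body_weight_g"])
        kept, report = apply_exclusion_criteria(df, crit)
        assert len(kept) == 2 and report.empty

    def test_empty_records(self):
        df = pd.DataFrame({"mouse_body_weight_g": []})
        crit = default_exclusion_criteria().subset(["mouse_body_weight_g"])
        kept, report = apply_exclusion_criteria(df, crit)
        assert kept.empty and report.empty

    def test_idempotent(self):
        df = pd.DataFrame({"rat_body_weight_g": [500.0, 600.0, 700.0]})
        crit = default_exclusion_criteria().subset(["rat_body_weight_g"])
        kept1, _ = apply_exclusion_criteria(df, crit)
        kept2, report2 = apply_exclusion_criteria(kept1, crit)
        pd.testing.assert_frame_equal(kept1, kept2)
        assert report2.empty

    def test_unknown_attribute_rejected(self):
        df = pd.DataFrame({"other": [1.0]})
        crit = default_exclusion_criteria().subset(["mouse_body_weight_g"])
        with pytest.raises(ValueError, match="missing"):
            apply_exclusion_criteria(df, crit)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            ExclusionCriteria({"x": (2.0, 1.0)})

    def test_all_published_windows_present(self):
        crit = default_exclusion_criteria()
        assert len(crit.windows) == 9
        assert crit.windows["piroxicam_6h_ng_cm2"] == (1200.0, 2000.0)


class TestSummaries:
    def test_single_replicate(self):
        reps, _ = generate_scenario("acd-control", n_replicates=1, seed=0)
        s = summarize_dataset(reps)
        np.testing.assert_array_equal(s.mean["acd-control"], reps[0].values)
        np.testing.assert_array_equal(s.sem["acd-control"], 0.0)

    def test_hand_computed_endpoint_sem(self):
        from dermakin import ObservationSeries

        t = np.array([0.0, 1.0])
        reps = [
            ObservationSeries(times=t, values=[0.0, v], scenario_id="x", replicate=i)
            for i, v in enumerate((10.0, 12.0, 14.0))
        ]
        s = summarize_dataset(reps)
        assert s.endpoint_mean("x") == pytest.approx(12.0)
        assert s.sem["x"][-1] == pytest.approx(2.0 / np.sqrt(3))

    def test_ratio_of_identical_scenarios_is_one(self):
        reps, _ = generate_scenario("acd-control", seed=5)
        s = summarize_dataset(reps)
        assert s.endpoint_ratio("acd-control", "acd-control") == 1.0

    def test_mismatched_grids_rejected(self):
        from dermakin import ObservationSeries

        a = ObservationSeries(times=[0.0, 1.0], values=[0, 1], scenario_id="x")
        b = ObservationSeries(
            times=[0.0, 2.0], values=[0, 1], scenario_id="x", replicate=1
        )
        with pytest.raises(ValueError, match="grids differ"):
            summarize_dataset([a, b])

    def test_noise_model_validation(self):
        with pytest.raises(ValueError):
            NoiseModel(cv_sample=-0.1)
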