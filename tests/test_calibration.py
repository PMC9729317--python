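import numpy as np
import pytest

import plrkit as pk
from plrkit import calibration as cal
from plrkit.engine import DeviceSettings, channel_response
from plrkit.exceptions import DomainError, InsufficientDataError
from plrkit.spectra import photopic_illuminance


class TestSamplingPlan:
    def test_default_step_65_gives_63_levels(self):
        plan = cal.sampling_plan()
        assert len(plan) == 63
        assert plan[-1] == 4095
        assert np.all(np.diff(plan) == 65)

    def test_full_step(self):
        assert cal.sampling_plan(4095) == [4095]

    def test_step_1024_excludes_4096(self):
        assert cal.sampling_plan(1024) == [1024, 2048, 3072]

    def test_include_zero(self):
        assert cal.sampling_plan(2048, include_zero=True) == [0, 2048]

    def test_step_out_of_range(self):
        with pytest.raises(DomainError):
            cal.sampling_plan(0)
        with pytest.raises(DomainError):
            cal.sampling_plan(5000)


class TestAcquire:
    def test_linear_channel_value_at_midlevel(self, linear_truth):
        table = cal.acquire_calibration(linear_truth, plan=[2048, 4095], seed=0)
        got = table.spectrum(0, 2048).values
        expected = (2048 / 4095) * linear_truth.primaries[0].values
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_null_primary_measures_zero(self):
        truth = pk.EngineGroundTruth.default(peak_irradiance=0.0)
        table = cal.acquire_calibration(truth, plan=[1000, 4095], seed=0)
        assert table.spectrum(3, 1000).values.max() == 0.0

    def test_same_seed_is_identical(self, curved_truth):
        t1 = cal.acquire_calibration(curved_truth, plan=[500, 4095], seed=9)
        t2 = cal.acquire_calibration(curved_truth, plan=[500, 4095], seed=9)
        for key in t1.records:
            np.testing.assert_array_equal(t1.records[key].values, t2.records[key].values)

    def test_table_csv_round_trip(self, linear_truth, tmp_path):
        table = cal.acquire_calibration(linear_truth, plan=[2048, 4095], seed=0)
        path = tmp_path / "table.csv"
        table.to_csv(path)
        back = cal.CalibrationTable.from_csv(path)
        np.testing.assert_allclose(
            back.spectrum(5, 2048).values, table.spectrum(5, 2048).values, rtol=1e-9
        )


class TestBuildContext:
    def test_midpoint_is_average_of_endpoint_spectra(self, linear_truth):
        table = cal.acquire_calibration(linear_truth, plan=[0, 4095], seed=0)
        ctx = cal.build_context(table)
        mid = ctx.spd(0, 2047.5).values
        expected = 0.5 * (table.spectrum(0, 0).values + table.spectrum(0, 4095).values)
        np.testing.assert_allclose(mid, expected, atol=1e-9)

    def test_missing_zero_level_is_anchored_at_zero(self, linear_truth):
        table = cal.acquire_calibration(linear_truth, plan=[2048, 4095], seed=0)
        ctx = cal.build_context(table)
        assert ctx.spd(0, 0).values.max() == 0.0
        # linear engine: anchored interpolation reproduces the true half-level
        np.testing.assert_allclose(
            ctx.spd(0, 1024).values,
            (1024 / 4095) * linear_truth.primaries[0].values,
            atol=1e-9,
        )

    def test_measured_level_returned_exactly(self, curved_ctx, curved_truth):
        table_level = 65 * 17
        got = curved_ctx.spd(4, table_level).values
        expected = channel_response(curved_truth, 4, table_level) * curved_truth.primaries[4].values
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_lux_lookup_monotone_over_all_4096_entries(self, curved_ctx):
        for led in range(10):
            assert np.all(np.diff(curved_ctx.lux[led]) >= -1e-12)

    def test_insufficient_levels_rejected(self, linear_truth):
        table = cal.acquire_calibration(linear_truth, plan=[4095], seed=0)
        del table.records[(2, 4095)]
        with pytest.raises(InsufficientDataError):
            cal.build_context(table)

    def test_save_load_round_trip(self, curved_ctx, tmp_path):
        curved_ctx.save(tmp_path / "ctx")
        back = cal.CalibrationContext.load(tmp_path / "ctx")
        s = DeviceSettings.single(6, 1234)
        np.testing.assert_allclose(
            back.predict_spd(s).values, curved_ctx.predict_spd(s).values, rtol=1e-9
        )


class TestPredictSpd:
    def test_all_zero_predicts_dark_corrected_zero(self, curved_ctx):
        assert curved_ctx.predict_spd(DeviceSettings.zeros()).values.max() == 0.0

    def test_knot_spectrum_reproduced(self, curved_ctx, curved_truth):
        s = DeviceSettings.single(9, 65 * 30)
        got = curved_ctx.predict_spd(s).values
        expected = channel_response(curved_truth, 9, 65 * 30) * curved_truth.primaries[9].values
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_random_settings_match_simulator_within_one_percent(self, curved_ctx, curved_truth, rng):
        for _ in range(20):
            s = DeviceSettings(tuple(int(v) for v in rng.integers(0, 4096, 10)))
            pred = curved_ctx.predict_spd(s).total
            true = pk.simulate_output(curved_truth, s).total
            if true > 0:
                assert abs(pred - true) / true < 0.01

    def test_additive_and_homogeneous_against_simulator(self, linear_ctx, linear_truth):
        s1 = DeviceSettings.single(0, 1000)
        s2 = DeviceSettings.single(5, 2000)
        both = DeviceSettings(tuple(a + b for a, b in zip(s1, s2)))
        lhs = linear_ctx.predict_spd(both).values
        rhs = linear_ctx.predict_spd(s1).values + linear_ctx.predict_spd(s2).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)
        truth_out = pk.simulate_output(linear_truth, both).values
        np.testing.assert_allclose(lhs, truth_out, atol=1e-9)


class TestFitCurves:
    def test_linear_channel_recovers_identity(self, linear_ctx):
        curves = cal.fit_curves(linear_ctx)
        for c in curves:
            assert c.alpha == pytest.approx(1.0, abs=1e-3)
            assert c.beta == pytest.approx(1.0, abs=1e-3)

    def test_planted_shape_parameters_recovered(self, curved_ctx):
        curves = cal.fit_curves(curved_ctx)
        for c in curves:
            assert c.alpha == pytest.approx(2.0, abs=1e-3)
            assert c.beta == pytest.approx(3.0, abs=1e-3)

    def test_scale_is_max_illuminance(self, curved_ctx, curved_truth):
        curves = cal.fit_curves(curved_ctx)
        lux_max = photopic_illuminance(
            pk.simulate_output(curved_truth, DeviceSettings.single(0, 4095))
        )
        assert curves[0].scale == pytest.approx(lux_max, rel=1e-6)

    def test_noisy_recovery_within_five_percent(self):
        # spectrometer noise giving ~1 percent illuminance CV
        model = pk.engine.SpectrometerModel(read_noise_sd=2.0)
        truth = pk.EngineGroundTruth.default(alpha=2.0, beta=3.0)
        alphas, betas = [], []
        for seed in range(10):
            table = cal.acquire_calibration(
                truth, plan=cal.sampling_plan(130), seed=seed, spectrometer=model
            )
            curves = cal.fit_curves(cal.build_context(table))
            alphas.extend(c.alpha for c in curves)
            betas.extend(c.beta for c in curves)
        assert np.mean(alphas) == pytest.approx(2.0, rel=0.05)
        assert np.mean(betas) == pytest.approx(3.0, rel=0.05)

    def test_curves_yaml_round_trip(self, curved_ctx, tmp_path):
        curves = cal.fit_curves(curved_ctx)
        cal.save_curves(curves, tmp_path / "curves.yaml")
        back = cal.load_curves(tmp_path / "curves.yaml")
        assert back[3].alpha == pytest.approx(curves[3].alpha)


class TestOptimise:
    def test_endpoints(self, curved_ctx):
        curves = cal.fit_curves(curved_ctx)
        assert cal.optimise_profile(curves, [0.0] * 10).intensities == (0,) * 10
        assert cal.optimise_profile(curves, [1.0] * 10).intensities == (4095,) * 10

    def test_linear_half_output_is_midscale(self, linear_ctx):
        curves = cal.fit_curves(linear_ctx)
        s = cal.optimise_profile(curves, [0.5] * 10)
        assert all(v == 2048 for v in s)  # round(0.5 * 4095)

    def test_forward_round_trip_within_quantisation(self, curved_ctx):
        curves = cal.fit_curves(curved_ctx)
        for target in [0.01, 0.1, 0.5, 0.9, 0.99]:
            s = cal.optimise_profile(curves, [target] * 10)
            for c, v in zip(curves, s):
                # a one-step error in s propagates through the curve slope
                slope = max(1.0, 4095 * (c.forward((v + 1) / 4095) - c.forward((v - 1) / 4095)) / 2)
                assert abs(c.forward(v / 4095) - target) <= 2.0 / 4095 * slope

    def test_out_of_range_desired_rejected(self, curved_ctx):
        curves = cal.fit_curves(curved_ctx)
        with pytest.raises(DomainError):
            cal.optimise_profile(curves, [1.5] * 10)


class TestInterpolationConvergence:
    def test_lookup_error_shrinks_quadratically(self, curved_truth):
        # halving the plan step should shrink the worst-case illuminance
        # lookup error at roughly second order (smooth beta-CDF curve)
        steps = [512, 256, 128]
        errors = []
        for step in steps:
            table = cal.acquire_calibration(curved_truth, plan=cal.sampling_plan(step), seed=0)
            ctx = cal.build_context(table)
            query = np.arange(0, 4096, 37)
            true_lux = np.array(
                [
                    photopic_illuminance(
                        pk.simulate_output(curved_truth, DeviceSettings.single(0, int(q)))
                    )
                    for q in query
                ]
            )
            errors.append(np.max(np.abs(ctx.lux[0][query] - true_lux)))
        order = np.polyfit(np.log(steps), np.log(errors), 1)[0]
        assert order >= 1.8
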