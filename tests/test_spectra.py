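import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plrkit as pk
from plrkit import cie
from plrkit.exceptions import DomainError, GridError, UnitsError
from plrkit.spectra import RADIANCE, Spectrum


GRID = cie.DEFAULT_GRID


class TestResample:
    def test_identity_on_same_grid(self):
        s = Spectrum.gaussian(500, 30)
        out = pk.resample(s, GRID)
        np.testing.assert_array_equal(out.values, s.values)

    def test_constant_restricts_to_subgrid(self):
        s = Spectrum(GRID, np.full_like(GRID, 2.0))
        sub = np.arange(450.0, 551.0, 5.0)
        np.testing.assert_allclose(pk.resample(s, sub).values, 2.0)

    def test_linear_segment_closed_form(self):
        # triangle peaking at 500 nm sampled every 10 nm; the 1 nm resample at
        # 505 nm must sit on the straight line between the 500 and 510 knots
        wl = np.arange(450.0, 551.0, 10.0)
        vals = np.maximum(0.0, 1.0 - np.abs(wl - 500.0) / 30.0)
        s = Spectrum(wl, vals)
        fine = pk.resample(s, np.arange(450.0, 551.0, 1.0))
        v500 = 1.0
        v510 = 1.0 - 10.0 / 30.0
        expected = v500 + (v510 - v500) * 0.5
        i = np.where(fine.wavelengths_nm == 505.0)[0][0]
        assert fine.values[i] == pytest.approx(expected, abs=1e-12)

    def test_out_of_support_is_zero(self):
        s = Spectrum(np.arange(500.0, 551.0), np.ones(51))
        out = pk.resample(s, np.arange(400.0, 601.0))
        assert out.values[out.wavelengths_nm < 500].max() == 0.0

    def test_bad_grid_rejected(self):
        s = Spectrum.gaussian(500, 30)
        with pytest.raises(GridError):
            pk.resample(s, np.array([500.0, 499.0, 501.0]))
        with pytest.raises(GridError):
            pk.resample(s, np.arange(200.0, 400.0))


class TestWeightedIntegral:
    def test_zero_spectrum(self):
        w = cie.photopic_vlambda()
        assert pk.weighted_integral(Spectrum.zeros(), w) == 0.0

    def test_rectangle_rule_sample_count_convention(self):
        # unit spectrum x unit weight over 400-500 nm at 1 nm: one term per
        # sample -> 101, not 100
        wl = np.arange(400.0, 501.0, 1.0)
        w = cie.WeightingFunction("unit", wl, np.ones_like(wl))
        s = Spectrum(wl, np.ones_like(wl))
        assert pk.weighted_integral(s, w) == pytest.approx(101.0)

    def test_matches_independent_loop_sum(self, rng):
        # independently coded per-sample summation oracle on random spectra
        w = cie.alpha_opic("melanopic")
        for _ in range(50):
            vals = rng.uniform(0, 2, GRID.size)
            s = Spectrum(GRID, vals)
            expected = 0.0
            weights = np.interp(GRID, w.wavelengths_nm, w.weights)
            for i in range(GRID.size):  # Δλ = 1 nm everywhere on this grid
                expected += vals[i] * weights[i] * 1.0
            got = pk.weighted_integral(s, w)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_disjoint_support_warns_and_returns_zero(self):
        w = cie.WeightingFunction("narrow", np.arange(700.0, 711.0), np.ones(11))
        s = Spectrum(np.arange(400.0, 411.0), np.ones(11))
        with pytest.warns(UserWarning, match="disjoint"):
            assert pk.weighted_integral(s, w) == 0.0

    @given(a=st.floats(0.1, 50.0), b=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_linearity_in_amplitude_and_addition(self, a, b):
        w = cie.photopic_vlambda()
        rng = np.random.default_rng(7)
        s1 = Spectrum(GRID, rng.uniform(0, 1, GRID.size))
        s2 = Spectrum(GRID, rng.uniform(0, 1, GRID.size))
        lhs = pk.weighted_integral(Spectrum(GRID, a * s1.values + b * s2.values), w)
        rhs = a * pk.weighted_integral(s1, w) + b * pk.weighted_integral(s2, w)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestAopic:
    def test_zero_spectrum_all_zero(self):
        a = pk.aopic_irradiance(Spectrum.zeros())
        assert np.all(a.as_array() == 0.0)

    def test_deep_red_barely_drives_melanopsin(self):
        a = pk.aopic_irradiance(Spectrum.monochromatic(660.0))
        assert a.mel < 0.01 * a.lc

    def test_doubling_doubles_every_component(self):
        s = Spectrum.gaussian(480, 30)
        a1 = pk.aopic_irradiance(s).as_array()
        a2 = pk.aopic_irradiance(s.scaled(2.0)).as_array()
        np.testing.assert_allclose(a2, 2.0 * a1, rtol=1e-12)

    def test_counts_spectrum_rejected(self):
        s = Spectrum(GRID, np.ones_like(GRID), units="counts")
        with pytest.raises(UnitsError):
            pk.aopic_irradiance(s)

    def test_adding_power_never_decreases_any_component(self, rng):
        base = Spectrum(GRID, rng.uniform(0, 1, GRID.size))
        before = pk.aopic_irradiance(base).as_array()
        for wl in rng.uniform(380, 780, 10):
            bumped = base + Spectrum.monochromatic(wl, 0.5)
            after = pk.aopic_irradiance(bumped).as_array()
            assert np.all(after >= before - 1e-15)

    def test_melanopic_peak_position(self):
        assert 480.0 < cie.alpha_opic("melanopic").peak_nm < 500.0


class TestPhotometry:
    def test_zero_spectrum_zero_lux(self):
        assert pk.photopic_illuminance(Spectrum.zeros()) == 0.0

    def test_monochromatic_555_defines_the_lumen(self):
        # 1 W/m^2 in the 555 nm bin -> 683 lx by the definition V(555)=1
        lux = pk.photopic_illuminance(Spectrum.monochromatic(555.0, 1.0))
        assert lux == pytest.approx(683.0, rel=1e-9)

    def test_lux_scales_linearly(self):
        s = Spectrum.gaussian(550, 40)
        assert pk.photopic_illuminance(s.scaled(3.0)) == pytest.approx(
            3.0 * pk.photopic_illuminance(s), rel=1e-12
        )


class TestChromaticity:
    def test_equal_energy_white(self):
        x, y = pk.chromaticity_xy(Spectrum(GRID, np.ones_like(GRID)))
        assert x == pytest.approx(1.0 / 3.0, abs=0.01)
        assert y == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_scale_invariance(self):
        s = Spectrum.gaussian(480, 20)
        assert pk.chromaticity_xy(s) == pytest.approx(pk.chromaticity_xy(s.scaled(7.3)))

    def test_narrowband_on_spectral_locus(self):
        # 470 nm line lands at the chromaticity of the raw CMF row
        xy = pk.chromaticity_xy(Spectrum.monochromatic(470.0))
        xb, yb, zb = cie.cie1931_cmfs(np.array([470.0]))
        s = xb[0] + yb[0] + zb[0]
        assert xy == pytest.approx((xb[0] / s, yb[0] / s), rel=1e-9)

    def test_zero_spectrum_undefined(self):
        with pytest.raises(DomainError):
            pk.chromaticity_xy(Spectrum.zeros())


class TestBlueLightHazard:
    def test_zero_radiance_within_limit(self):
        h = pk.blue_light_hazard(Spectrum.zeros(units=RADIANCE), exposure_s=1.0)
        assert h.l_b == 0.0 and h.within_limit

    def test_pupil_corrected_long_exposure_limit(self):
        # factor 6 divides the 100 W/m^2/sr radiance limit; the report
        # truncates 16.66... to one decimal
        h = pk.blue_light_hazard(
            Spectrum.zeros(units=RADIANCE), exposure_s=2e4, pupil_correction_factor=6.0
        )
        assert h.exposure_limit == pytest.approx(100.0 / 6.0)
        assert h.report()["exposure_limit"] == 16.6

    def test_short_exposure_uses_dose_limit(self):
        h = pk.blue_light_hazard(Spectrum.zeros(units=RADIANCE), exposure_s=100.0)
        assert h.exposure_limit == pytest.approx(1.0e6)
        assert h.limit_units.startswith("J")

    def test_monochromatic_line_single_term_sum(self):
        b = cie.blue_light_hazard_function()
        peak_wl = b.peak_nm
        r = 3.7
        grid = np.arange(300.0, 701.0, 1.0)
        s = Spectrum.monochromatic(peak_wl, r, wl=grid, units=RADIANCE)
        h = pk.blue_light_hazard(s, exposure_s=1.0)
        assert h.l_b == pytest.approx(r * b.weights.max() * 1.0, rel=1e-9)

    def test_within_limit_flips_exactly_at_the_limit(self):
        grid = np.arange(300.0, 701.0, 1.0)
        b = cie.blue_light_hazard_function()
        for eps, expect in [(-1e-9, True), (1e-9, False)]:
            target_lb = 100.0 + eps
            s = Spectrum.monochromatic(b.peak_nm, target_lb / b.weights.max(), wl=grid, units=RADIANCE)
            h = pk.blue_light_hazard(s, exposure_s=2e4)
            assert h.within_limit is expect

    def test_irradiance_input_rejected(self):
        with pytest.raises(UnitsError):
            pk.blue_light_hazard(Spectrum.zeros(), exposure_s=1.0)


class TestPupilCorrectionFactor:
    @pytest.mark.parametrize(
        "ref,act,expected",
        [(3.0, 7.0, 5.4), (5.0, 5.0, 1.0), (3.0, 6.0, 4.0)],
    )
    def test_area_ratio(self, ref, act, expected):
        assert round(pk.pupil_correction_factor(ref, act), 1) == expected

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(DomainError):
            pk.pupil_correction_factor(0.0, 7.0)


class TestSpectrumType:
    def test_invariants_enforced(self):
        with pytest.raises(GridError):
            Spectrum(np.array([400.0, 400.0, 500.0]), np.zeros(3))
        with pytest.raises(GridError):
            Spectrum(GRID, np.ones(GRID.size - 1))
        with pytest.raises(GridError):
            Spectrum(GRID, np.full(GRID.size, np.nan))
        with pytest.raises(UnitsError):
            Spectrum(GRID, np.zeros(GRID.size), units="furlongs")

    def test_csv_round_trip(self, tmp_path):
        s = Spectrum.gaussian(520, 25, 0.3, units=RADIANCE)
        path = tmp_path / "spec.csv"
        pk.spectra.write_spectrum_csv(s, path)
        back = pk.spectra.read_spectrum_csv(path)
        assert back.units == RADIANCE
        np.testing.assert_allclose(back.values, s.values, rtol=1e-9)
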