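"""Fluid-sphere model: limits, monotonicity, inversion round-trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zoosonde.scattering import (
    FluidSphereParams,
    SizeBand,
    alpha_pis,
    delta_ts,
    invert_size,
    ka,
    reflection_coefficient,
    sigma_bs,
    sound_speed,
    target_strength,
)


class TestSoundSpeed:
    def test_survey_conditions_give_1508(self):
        # 14.9 degC, 35.7 PSU -> 1508 m/s to the nearest 0.1
        assert sound_speed(14.9, 35.7, 50.0) == pytest.approx(1508.0, abs=0.05)

    def test_cold_surface_bracket(self):
        assert 1440.0 < sound_speed(0.0, 35.0, 0.0) < 1460.0

    def test_monotone_in_temperature(self):
        cs = [sound_speed(t, 35.0, 10.0) for t in range(0, 21)]
        assert np.all(np.diff(cs) > 0)

    @pytest.mark.parametrize("t,s,d", [(-5, 35, 0), (20, 50, 0), (20, 35, -1)])
    def test_out_of_range_rejected(self, t, s, d):
        with pytest.raises(ValueError):
            sound_speed(t, s, d)


class TestContrastTerms:
    def test_reflection_coefficient_survey_params(self, params):
        # (1.02*1.058 - 1) / (1.02*1.058 + 1)
        assert reflection_coefficient(params) == pytest.approx(0.03807, abs=5e-5)

    def test_no_contrast_no_reflection(self):
        p = FluidSphereParams(g=1.0, h=1.0)
        assert reflection_coefficient(p) == 0.0
        assert alpha_pis(p) == 0.0

    def test_alpha_pis_survey_params(self, params):
        assert alpha_pis(params) == pytest.approx(-0.04797, abs=5e-5)

    @pytest.mark.parametrize("g", [0.95, 1.0, 1.05])
    def test_reflection_sign_tracks_impedance(self, g):
        p = FluidSphereParams(g=g, h=1.0)
        assert np.sign(reflection_coefficient(p)) == np.sign(g * 1.0 - 1.0)


class TestSigmaBs:
    def test_rayleigh_limit(self, params):
        # at ka120 = 0.01 the full model matches the a^2 (ka)^4 alpha^2 form
        a_mm = 0.01 / params.wavenumber(params.f_high_khz) * 1e3
        rayleigh = (a_mm * 1e-3) ** 2 * 0.01**4 * alpha_pis(params) ** 2
        assert sigma_bs(a_mm, params.f_high_khz, params) == pytest.approx(
            rayleigh, rel=1e-3
        )

    def test_rayleigh_regime_within_half_percent(self, params):
        for kav in (0.02, 0.03, 0.05):
            a_mm = kav / params.wavenumber(38.0) * 1e3
            rayleigh = (a_mm * 1e-3) ** 2 * kav**4 * alpha_pis(params) ** 2
            assert sigma_bs(a_mm, 38.0, params) == pytest.approx(rayleigh, rel=5e-3)

    def test_geometric_plateau(self, params):
        # ka >> 1: sigma_bs -> a^2 R^2 / 4
        for kav in (20.0, 50.0):
            a_m = kav / params.wavenumber(120.0)
            plateau = a_m**2 * reflection_coefficient(params) ** 2 / 4.0
            assert sigma_bs(a_m * 1e3, 120.0, params) == pytest.approx(plateau, rel=0.02)

    def test_f4_scaling_near_rayleigh(self, params):
        ratio = sigma_bs(0.5, 120.0, params) / sigma_bs(0.5, 38.0, params)
        assert ratio == pytest.approx((120.0 / 38.0) ** 4, rel=0.03)

    def test_strictly_increasing_in_size(self, params):
        a = np.linspace(0.1, 5.0, 200)
        s = sigma_bs(a, 120.0, params)
        assert np.all(np.diff(s) > 0)

    def test_negative_size_rejected(self, params):
        with pytest.raises(ValueError):
            sigma_bs(-1.0, 120.0, params)


class TestTargetStrength:
    def test_db_definition(self, params):
        # find the size whose sigma_bs is 1e-10 m^2; its TS must be -100 dB
        a = 0.8
        ts = target_strength(a, 120.0, params)
        assert ts == pytest.approx(10 * math.log10(sigma_bs(a, 120.0, params)))

    def test_rayleigh_doubling_slope(self, params):
        # deep Rayleigh regime: sigma ~ a^6, so TS(2a) - TS(a) = 10 log10 64
        ts1 = target_strength(0.005, 38.0, params)
        ts2 = target_strength(0.010, 38.0, params)
        assert ts2 - ts1 == pytest.approx(10 * math.log10(64), abs=0.01)

    def test_monotone_in_size(self, params):
        a = np.linspace(0.1, 5.0, 100)
        assert np.all(np.diff(target_strength(a, 38.0, params)) > 0)


class TestDeltaTs:
    def test_rayleigh_ceiling(self, params):
        # esr -> 0: dTS -> 40 log10(120/38) = 19.98 dB
        assert delta_ts(0.01, params) == pytest.approx(
            40 * math.log10(120 / 38), abs=0.05
        )

    def test_half_millimetre_band_edge(self, params):
        # the 0.5 mm edge of the copepod window sits at ~19.7 dB
        assert delta_ts(0.5, params) == pytest.approx(19.7, abs=0.3)

    def test_strictly_decreasing_in_invertible_band(self, params):
        a_max = 2.0 / params.wavenumber(params.f_high_khz) * 1e3  # ka120 = 2
        a = np.linspace(0.05, a_max, 300)
        d = [delta_ts(x, params) for x in a]
        assert np.all(np.diff(d) < 0)


class TestKa:
    def test_band_edge_value(self, params):
        # 0.5 mm at the geometric-mean frequency -> ka = 0.14
        assert round(ka(0.5, params), 2) == 0.14

    def test_linear_in_size(self, params):
        assert ka(2.0, params) == pytest.approx(2 * ka(1.0, params))

    def test_geometric_mean_frequency(self, params):
        assert params.f_geometric_khz == pytest.approx(math.sqrt(38 * 120), rel=1e-12)


class TestInvertSize:
    def test_round_trip_identity(self, params, band):
        inv = invert_size(delta_ts(1.0, params), params, band)
        assert not inv.clamped
        assert inv.esr_mm == pytest.approx(1.0, abs=1e-3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=7.5, max_value=19.5))
    def test_mutual_inverse_on_band(self, delta_db):
        p = FluidSphereParams()
        b = SizeBand.from_delta_bounds(p)
        inv = invert_size(delta_db, p, b)
        assert delta_ts(inv.esr_mm, p) == pytest.approx(delta_db, abs=5e-3)

    def test_above_band_clamps_to_small_edge(self, params, band):
        inv = invert_size(21.0, params, band)
        assert inv.clamped and inv.esr_mm == band.esr_min_mm

    def test_below_band_clamps_to_large_edge(self, params, band):
        inv = invert_size(3.0, params, band)
        assert inv.clamped and inv.esr_mm == band.esr_max_mm

    def test_band_edges_follow_model(self, params, band):
        # the dTS window maps to its model-consistent ESR image
        assert delta_ts(band.esr_min_mm, params) == pytest.approx(19.7, abs=1e-3)
        assert delta_ts(band.esr_max_mm, params) == pytest.approx(7.0, abs=1e-3)

    def test_non_monotone_band_rejected(self):
        with pytest.raises(ValueError):
            SizeBand(esr_min_mm=1.0, esr_max_mm=2.0, delta_db_at_min=7.0, delta_db_at_max=19.7)

    def test_band_above_ceiling_rejected(self, params):
        with pytest.raises(ValueError):
            SizeBand.from_delta_bounds(params, delta_db_hi=20.5, delta_db_lo=7.0)


def test_unit_consistency_under_frequency_scaling():
    """ka and dTS depend on f/c only through k: rescaling both is a no-op."""
    p1 = FluidSphereParams(c=1508.0)
    p2 = FluidSphereParams(c=1450.0)
    a2 = 0.7 * 1450.0 / 1508.0  # same ka
    assert ka(0.7, p1) == pytest.approx(ka(a2, p2), rel=1e-12)
    assert delta_ts(0.7, p1) == pytest.approx(delta_ts(a2, p2), rel=1e-9)
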