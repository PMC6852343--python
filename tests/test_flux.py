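"""Evaporative-flux K_leaf and psychrometric g_min computations."""

import numpy as np
import pytest

from leafcable.flux import (
    FluxError,
    LeafEnvironment,
    MassTimeSeries,
    gmin,
    kleaf_from_flux,
    saturation_vapor_concentration,
    transpiration_rate,
)
from leafcable.units import DomainError


def make_series(slope_g_s, area=0.002, n=180, step=10.0, m0=20.0, noise_sd=0.0, seed=0):
    t = np.arange(n) * step
    m = m0 + slope_g_s * t
    if noise_sd:
        m = m + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return MassTimeSeries(times_s=t, masses_g=m, leaf_area_m2=area)


class TestTranspiration:
    def test_reference_slope(self):
        # 0.1 mg per 10 s over 0.002 m2 -> 0.278 mmol m-2 s-1
        s = make_series(-1e-5)
        e = transpiration_rate(s, window=(0.0, s.times_s[-1]))
        assert e == pytest.approx(0.2776, rel=1e-3)

    def test_noisy_slope_recovered(self):
        s = make_series(-1e-5, noise_sd=1e-4, seed=2)
        e = transpiration_rate(s, window=(0.0, s.times_s[-1]))
        assert e == pytest.approx(0.2776, rel=0.05)

    def test_constant_mass_is_an_error(self):
        s = make_series(0.0)
        with pytest.raises(FluxError):
            transpiration_rate(s, window=(0.0, 1e9))

    def test_gaining_mass_is_an_error(self):
        s = make_series(1e-6)
        with pytest.raises(FluxError):
            transpiration_rate(s, window=(0.0, 1e9))

    def test_invariance_to_mass_and_time_offsets(self):
        s = make_series(-2e-5)
        shifted = MassTimeSeries(s.times_s + 1234.5, s.masses_g + 7.7, s.leaf_area_m2)
        w0 = (s.times_s[0], s.times_s[-1])
        w1 = (shifted.times_s[0], shifted.times_s[-1])
        assert transpiration_rate(s, window=w0) == pytest.approx(
            transpiration_rate(shifted, window=w1), rel=1e-12
        )

    def test_stabilization_segment_discarded(self):
        # steeper equilibration slope for the first 600 s must not bias E
        t = np.arange(0.0, 2400.0, 10.0)
        slope = -1e-5
        m = np.where(t <= 600, 20.0 + 2 * slope * t, 20.0 + 2 * slope * 600 + slope * (t - 600))
        s = MassTimeSeries(t, m, 0.002)
        assert transpiration_rate(s) == pytest.approx(0.2776, rel=1e-3)

    def test_short_window_rejected(self):
        s = make_series(-1e-5, n=30)
        with pytest.raises(FluxError):
            transpiration_rate(s, window=(0.0, 15.0))

    def test_invalid_series_rejected(self):
        with pytest.raises(DomainError):
            MassTimeSeries(np.array([0.0, 0.0, 1.0]), np.array([1.0, 1.0, 1.0]), 0.001)


class TestKleaf:
    @pytest.mark.parametrize(
        "e, psi, expected", [(1.0, -0.5, 2.0), (0.278, -0.5, 0.556)]
    )
    def test_ratio(self, e, psi, expected):
        assert kleaf_from_flux(e, psi) == pytest.approx(expected, rel=1e-3)

    def test_exact_inverse_identity(self):
        e, psi = 0.7483, -0.5
        assert kleaf_from_flux(e, psi) * -psi == e

    def test_printed_subset_pair(self):
        # K_leaf = 0.756 at Psi = -0.99 implies E = 0.748 mmol m-2 s-1
        e = 0.756 * 0.99
        assert kleaf_from_flux(e, -0.99) == pytest.approx(0.756, rel=1e-12)
        assert e == pytest.approx(0.748, abs=5e-4)

    def test_nonnegative_psi_rejected(self):
        with pytest.raises(DomainError):
            kleaf_from_flux(1.0, 0.0)


class TestVapor:
    @pytest.mark.parametrize(
        "t_c, expected", [(25.0, 0.0230), (0.0, 0.0049)]
    )
    def test_reference_concentrations(self, t_c, expected):
        assert saturation_vapor_concentration(t_c) == pytest.approx(expected, abs=2e-4)

    def test_monotone_increasing(self):
        c = [saturation_vapor_concentration(t) for t in np.arange(0.0, 51.0, 1.0)]
        assert all(a < b for a, b in zip(c, c[1:]))


class TestGmin:
    ENV = LeafEnvironment(25.0, 25.0, 0.5)

    def test_worked_example(self):
        assert gmin(1e-9, 0.001, self.ENV) == pytest.approx(4.34e-5, rel=0.005)

    def test_saturated_air_rejected(self):
        with pytest.raises(DomainError):
            gmin(1e-9, 0.001, LeafEnvironment(25.0, 25.0, 1.0))

    def test_scales_inversely_with_area_and_dc(self):
        base = gmin(1e-9, 0.001, self.ENV)
        assert gmin(1e-9, 0.002, self.ENV) == pytest.approx(base / 2, rel=1e-12)
        half_dc = LeafEnvironment(25.0, 25.0, 0.75)  # halves dC at equal temps
        assert gmin(1e-9, 0.001, half_dc) == pytest.approx(2 * base, rel=1e-12)

    def test_invalid_humidity_rejected(self):
        with pytest.raises(DomainError):
            LeafEnvironment(25.0, 25.0, 1.4)
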