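"""Closed-form gas, shock and blast relations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from opcflow.gas_core import (
    AIR,
    FriedlanderWave,
    GasConstants,
    GasState,
    friedlander_impulse,
    friedlander_pressure,
    isentropic_temperature,
    normal_shock_state,
    peak_dynamic_pressure,
    shock_mach_from_overpressure,
    sound_speed,
    tnt_equivalent_mass,
)


class TestSoundSpeed:
    @pytest.mark.parametrize("T, expected", [
        (293.15, 343.2),      # laboratory ambient
        (213.15, 292.7),      # the cold jet minimum (-60 degC)
    ])
    def test_values(self, T, expected):
        assert sound_speed(T) == pytest.approx(expected, abs=0.05)

    def test_sqrt_homogeneity(self):
        assert sound_speed(4 * 300.0) == pytest.approx(2 * sound_speed(300.0),
                                                       rel=1e-14)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sound_speed(0.0)


class TestDynamicPressurePartition:
    def test_moderate_blast(self):
        # 103 kPa static overpressure partitions to ~33 kPa of blast wind
        assert peak_dynamic_pressure(103e3) == pytest.approx(33e3, rel=0.02)

    def test_strong_blast_near_equality(self):
        # near the fireball edge the static and dynamic peaks are comparable
        q = peak_dynamic_pressure(480e3)
        assert q == pytest.approx(480e3, rel=0.05)

    def test_zero(self):
        assert peak_dynamic_pressure(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            peak_dynamic_pressure(-1.0)

    def test_weak_blast_negligible_wind(self):
        assert peak_dynamic_pressure(10e3) < 500.0

    def test_weak_limit_coefficient(self):
        # q / dp^2 -> 5 / (14 p_amb) as dp -> 0
        dp = 1e3
        assert peak_dynamic_pressure(dp) / dp ** 2 == pytest.approx(
            5.0 / (14.0 * AIR.p_amb), rel=2e-3)

    def test_convex_increasing(self):
        dps = np.linspace(0.0, 600e3, 200)
        q = np.array([peak_dynamic_pressure(d) for d in dps])
        assert np.all(np.diff(q) > 0)
        assert np.all(np.diff(q, 2) > 0)

    def test_consistent_with_full_jump_conditions(self):
        # q from the closed form equals rho2 u2^2 / 2 behind the shock
        for dp in (10e3, 103e3, 480e3, 1e6):
            Ms = shock_mach_from_overpressure(dp)
            post = normal_shock_state(Ms)
            assert post.p - AIR.p_amb == pytest.approx(dp, rel=1e-12)
            assert peak_dynamic_pressure(dp) == pytest.approx(
                post.dynamic_pressure, rel=1e-6)


class TestShockMach:
    def test_acoustic_limit(self):
        assert shock_mach_from_overpressure(0.0) == 1.0

    def test_one_atmosphere(self):
        assert shock_mach_from_overpressure(101.325e3) == pytest.approx(
            math.sqrt(1 + 6 / 7), rel=1e-12)

    def test_monotone(self):
        assert shock_mach_from_overpressure(480e3) > \
            shock_mach_from_overpressure(103e3)


class TestFriedlander:
    def test_endpoints(self):
        w = FriedlanderWave(dp_peak=20e3, t_pos=5e-3, b=1.2)
        assert friedlander_pressure(0.0, w) == w.dp_peak
        assert friedlander_pressure(w.t_pos, w) == pytest.approx(0.0, abs=1e-9)

    def test_negative_phase_returns_to_zero(self):
        w = FriedlanderWave(dp_peak=20e3, t_pos=5e-3, b=1.0)
        t = np.linspace(1.01 * w.t_pos, 10 * w.t_pos, 400)
        p = friedlander_pressure(t, w)
        assert np.all(p < 0)
        assert abs(p[-1]) < abs(p[0])

    def test_triangle_impulse_b0(self):
        w = FriedlanderWave(dp_peak=20e3, t_pos=5e-3, b=0.0)
        assert friedlander_impulse(w) == pytest.approx(
            0.5 * 20e3 * 5e-3, rel=1e-12)

    @pytest.mark.parametrize("b", [0.3, 1.0, 2.7])
    def test_impulse_matches_quadrature(self, b):
        w = FriedlanderWave(dp_peak=35e3, t_pos=4e-3, b=b)
        oracle, _ = quad(lambda t: friedlander_pressure(t, w), 0.0, w.t_pos,
                         epsabs=1e-12, epsrel=1e-12)
        assert friedlander_impulse(w) == pytest.approx(oracle, rel=1e-8)

    def test_negative_time_rejected(self):
        w = FriedlanderWave(dp_peak=1e3, t_pos=1e-3)
        with pytest.raises(ValueError):
            friedlander_pressure(-1e-6, w)


class TestIsentropic:
    def test_identity(self):
        assert isentropic_temperature(50e3, 50e3, 300.0) == 300.0

    def test_driver_expansion_to_ambient(self):
        # venting the 239.3 kPa driver gas to ambient cools it strongly
        T = isentropic_temperature(101.325e3, 239.325e3, 293.0)
        assert T == pytest.approx(229.0, abs=1.0)

    def test_expansion_to_partial_vacuum_reaches_minus_60C(self):
        T = isentropic_temperature(80e3, 239.325e3, 293.0)
        assert T == pytest.approx(214.0, abs=1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            isentropic_temperature(-1.0, 2.0, 3.0)


class TestTntEquivalent:
    def test_zero(self):
        assert tnt_equivalent_mass(0.0, 1.0) == 0.0

    def test_bulge_volume_estimate(self):
        # hemispherical bulge of the aperture radius at the burst pressure
        V = 2.0 / 3.0 * math.pi * 0.07 ** 3
        m = tnt_equivalent_mass(138e3, V)
        assert m == pytest.approx(59.2e-6, rel=1e-3)

    def test_linearity_in_volume(self):
        assert tnt_equivalent_mass(5e4, 2e-3) == pytest.approx(
            2 * tnt_equivalent_mass(5e4, 1e-3), rel=1e-12)

    def test_yield_factor(self):
        assert tnt_equivalent_mass(5e4, 1e-3, yield_factor=0.4) == \
            pytest.approx(0.4 * tnt_equivalent_mass(5e4, 1e-3), rel=1e-12)


class TestStateTypes:
    def test_ideal_gas_closure_enforced(self):
        with pytest.raises(ValueError):
            GasState(p=101325.0, rho=1.0, T=300.0)

    def test_from_pT_closes_density(self):
        s = GasState.from_pT(101325.0, 293.15)
        assert s.rho == pytest.approx(AIR.rho_amb, rel=1e-12)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            GasConstants(gamma=0.9)
        with pytest.raises(ValueError):
            GasConstants(p_amb=-1.0)

    @given(st.floats(min_value=1e3, max_value=1e7),
           st.floats(min_value=150.0, max_value=2000.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_state_closure_property(self, p, T):
        s = GasState.from_pT(p, T)
        assert s.rho * AIR.R_air * s.T == pytest.approx(s.p, rel=1e-12)
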