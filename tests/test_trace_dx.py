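"""Pressure-record diagnostics."""

import numpy as np
import pytest

from opcflow.gas_core import FriedlanderWave, friedlander_pressure
from opcflow.trace_dx import (
    DiagnosticsConfig,
    PressureTrace,
    TraceRole,
    classify_shock,
    diagnose,
    impulse_integral,
    reverberation_period,
    rise_time_10_90,
    settling_time,
)

FS = 8e5


def _trace(samples, rate=FS, t0=0.0, role=TraceRole.static):
    return PressureTrace(channel_id="t", role=role, samples=samples,
                         sample_rate=rate, t0=t0)


def _friedlander_trace(dp=20e3, t_pos=2e-4, b=1.0, pre=1e-3, total=5e-3,
                       rate=FS, baseline=0.0):
    """Step-onset Friedlander with a quiet pre-trigger window."""
    t = np.arange(0.0, total, 1.0 / rate)
    x = np.zeros_like(t)
    m = t >= pre
    x[m] = friedlander_pressure(t[m] - pre, FriedlanderWave(dp, t_pos, b))
    return _trace(x + baseline)


class TestDiagnose:
    def test_friedlander_step_onset(self):
        rep = diagnose(_friedlander_trace())
        assert rep.peak_overpressure == pytest.approx(20e3, rel=0.01)
        assert rep.rise_time < 10e-6
        assert rep.is_shock_front
        assert rep.positive_phase_duration == pytest.approx(2e-4, rel=0.05)

    def test_ramp_onset_is_not_shock(self):
        t = np.arange(0.0, 10e-3, 1.0 / FS)
        ramp = 100e3 * np.clip(t / 1.5e-3, 0.0, 1.0)
        rep = diagnose(_trace(ramp))
        assert not rep.is_shock_front
        assert rep.rise_time == pytest.approx(0.8 * 1.5e-3, rel=0.05)

    def test_constant_trace_reports_zero_peak(self):
        rep = diagnose(_trace(np.full(4000, 3e3)))
        assert rep.peak_overpressure == 0.0
        assert not rep.is_shock_front

    def test_baseline_invariance(self):
        """A constant pre-trigger offset must not bias any quantity."""
        a = diagnose(_friedlander_trace(baseline=0.0))
        b = diagnose(_friedlander_trace(baseline=4.7e3))
        assert b.peak_overpressure == pytest.approx(a.peak_overpressure,
                                                    rel=1e-9)
        assert b.impulse == pytest.approx(a.impulse, rel=1e-6)
        assert b.rise_time == pytest.approx(a.rise_time, abs=1e-9)
        assert b.quasi_static_level == pytest.approx(a.quasi_static_level,
                                                     abs=1.0)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="1 ms"):
            diagnose(_trace(np.zeros(100)))

    @pytest.mark.parametrize("f", [500.0, 1300.0, 5000.0])
    def test_spectral_peak_recovery(self, f):
        """A ripple injected on an exponential decay is recovered within
        one FFT bin of the analysis window."""
        t = np.arange(0.0, 20e-3, 1.0 / FS)
        onset = t >= 0.2e-3
        x = np.zeros_like(t)
        x[onset] = (100e3 * np.exp(-(t[onset] - 0.2e-3) / 5e-3)
                    + 2e3 * np.sin(2 * np.pi * f * t[onset]))
        cfg = DiagnosticsConfig()
        rep = diagnose(_trace(x), cfg)
        bin_width = 1.0 / cfg.decay_window
        assert rep.dominant_frequency == pytest.approx(f, abs=bin_width)

    def test_downsampling_robust_for_jet_records(self):
        """800 kHz -> 100 kHz changes peak and impulse of a ramped (non-
        shock) record by under 1%."""
        t = np.arange(0.0, 30e-3, 1.0 / FS)
        x = (np.clip(t / 1.5e-3, 0, 1)
             * (120e3 * np.exp(-t / 6e-3) + 15e3))
        hi = _trace(x)
        lo = _trace(x[::8], rate=FS / 8)
        rep_hi, rep_lo = diagnose(hi), diagnose(lo)
        assert rep_lo.peak_overpressure == pytest.approx(
            rep_hi.peak_overpressure, rel=0.01)
        i_hi = impulse_integral(hi, (0.0, 25e-3))
        i_lo = impulse_integral(lo, (0.0, 25e-3))
        assert i_lo == pytest.approx(i_hi, rel=0.01)


class TestClassifyShock:
    def test_pure_step(self):
        x = np.zeros(4000)
        x[2000:] = 50e3
        assert classify_shock(_trace(x))

    def test_linear_ramp_1_5ms(self):
        t = np.arange(0.0, 5e-3, 1.0 / FS)
        assert not classify_shock(_trace(50e3 * np.clip(t / 1.5e-3, 0, 1)))


class TestImpulseIntegral:
    def test_rectangle(self):
        tr = _trace(np.full(8000, 10e3))  # 10 ms at 10 kPa
        assert impulse_integral(tr, (0.0, 10e-3)) == pytest.approx(100.0,
                                                                   rel=1e-3)

    def test_triangular_friedlander(self):
        # b = 0 triangle: 20 kPa over 5 ms -> 50 Pa s
        t = np.arange(0.0, 5e-3 + 1.25e-6, 1.0 / FS)
        x = 20e3 * (1 - t / 5e-3)
        assert impulse_integral(_trace(x), (0.0, 5e-3)) == pytest.approx(
            50.0, rel=1e-3)

    def test_antisymmetric_wave(self):
        t = np.arange(0.0, 10e-3, 1.0 / FS)
        x = 5e3 * np.sin(2 * np.pi * t / 10e-3)
        assert abs(impulse_integral(_trace(x), (0.0, 10e-3))) < 0.05

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            impulse_integral(_trace(np.zeros(1000)), (5e-3, 5e-3))


class TestPeriodAndSettling:
    def test_damped_sine_period(self):
        t = np.arange(0.0, 60e-3, 1.0 / FS)
        x = 15e3 + 3e3 * np.exp(-t / 30e-3) * np.sin(2 * np.pi * t / 8.5e-3)
        per = reverberation_period(_trace(x), window=(20e-3, 60e-3))
        assert per == pytest.approx(8.5e-3, rel=0.02)

    def test_settling_time(self):
        t = np.arange(0.0, 50e-3, 1.0 / FS)
        x = 15e3 + 100e3 * np.exp(-t / 5e-3)
        ts = settling_time(_trace(x), 15e3, 10e3)
        assert ts == pytest.approx(5e-3 * np.log(10.0), rel=0.01)

    def test_never_settles_rejected(self):
        with pytest.raises(ValueError):
            settling_time(_trace(np.linspace(0, 1e5, 2000)), 0.0, 1e3)


class TestTraceContainer:
    def test_rise_time_of_single_sample_step(self):
        x = np.zeros(2000)
        x[1000:] = 1e4
        assert rise_time_10_90(_trace(x)) <= 1.0 / FS

    def test_window_slice_bounds(self):
        tr = _trace(np.arange(1000.0))
        sl = tr.window_slice(0.0, 1e-4)
        assert sl.start == 0 and sl.stop == 81

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            _trace(np.array([1.0, np.nan]))
        with pytest.raises(ValueError):
            _trace(np.zeros(10), rate=-1.0)
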