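"""Synthetic sensor records and free-flight tracks.

Generates gauge-pressure records with the temporal structure the real
instrumentation suite produces, so every analysis stage can be exercised
(and its parameter recovery tested) without measured data:

* an on-axis stagnation record -- a ~20 kPa / 0.2 ms precursor wavelet,
  then the jet decay from the burst level toward the quasi-static level
  with a ~1.3 kHz ripple, converging in stages timed by the ~8.5 ms
  longitudinal reverberation;
* a static record fluctuating below 20 kPa with at least one partial-
  vacuum dip;
* a monotone driver blowdown record;
* free-field blast records (static Friedlander + dynamic-pressure channel);
* camera-style displacement tracks with frame-rate discretization and
  pixel noise.

All randomness (noise, the shock-vs-ramp onset draw) is governed by the
spec seed: the same seed reproduces the record bit for bit, and the
deterministic skeleton is identical across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .free_flight import TrackRecord
from .gas_core import AIR, FriedlanderWave, GasConstants, \
    friedlander_pressure, peak_dynamic_pressure
from .trace_dx import PressureTrace, TraceRole

__all__ = ["RecordSpec", "gen_opc_record", "gen_blast_record", "gen_track"]


@dataclass(frozen=True)
class RecordSpec:
    """Parameters of the synthetic chamber record suite.

    Amplitudes in Pa, durations in s.  ``jet_decay_tau`` of 6 ms puts the
    stagnation record within 10% of the quasi-static level in roughly
    18 ms; ``shock_fraction`` is the probability that the jet onset is a
    step (shock front) instead of the usual 1.5 ms ramp.
    """

    precursor: tuple = (20e3, 2e-4)
    jet_decay_tau: float = 6e-3
    ripple: tuple = (1300.0, 0.03)
    quasi_static: float = 15e3
    reverberation_period: float = 8.5e-3
    static_fluctuation_bound: float = 20e3
    vacuum_dip_depth: float = 5e3
    noise_sd: float = 200.0
    drift_rate: float = 0.0
    shock_fraction: float = 0.10
    seed: int = 0
    # skeleton details not part of the headline sensor figures
    jet_peak: float = 138e3
    jet_onset: float = 0.8e-3
    ramp_duration: float = 1.5e-3
    precursor_arrival: float = 0.4e-3
    reverb_amplitude: float = 3e3
    reverb_tau: float = 25e-3

    def __post_init__(self) -> None:
        if self.precursor[0] < 0 or self.quasi_static < 0 \
                or self.noise_sd < 0 or self.vacuum_dip_depth < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.precursor[1] <= 0 or self.jet_decay_tau <= 0 \
                or self.reverberation_period <= 0:
            raise ValueError("durations must be positive")
        if not 0.0 <= self.shock_fraction <= 1.0:
            raise ValueError("shock_fraction must lie in [0, 1]")


def _precursor(t: np.ndarray, spec: RecordSpec) -> np.ndarray:
    amp, dur = spec.precursor
    s = (t - spec.precursor_arrival) / dur
    pulse = amp * (1.0 - s) * np.exp(-s)
    return np.where((s >= 0.0) & (s <= 1.0), pulse, 0.0)


def _reverb(t: np.ndarray, spec: RecordSpec) -> np.ndarray:
    tr = t - spec.jet_onset
    sq = np.tanh(3.0 * np.sin(2.0 * np.pi * tr / spec.reverberation_period))
    return np.where(tr >= 0.0,
                    spec.reverb_amplitude * np.exp(-tr / spec.reverb_tau) * sq,
                    0.0)


def gen_opc_record(spec: RecordSpec, duration: float = 60e-3,
                   sample_rate: float = 8e5) -> dict:
    """Generate the three-channel chamber record suite.

    Returns a dict with keys ``stagnation``, ``static`` and ``driver``
    mapping to :class:`PressureTrace` objects sharing ``sample_rate``.
    Deterministic given ``spec.seed``.
    """
    if duration < 30e-3:
        raise ValueError("duration must be at least 30 ms for full structure")
    rng = np.random.default_rng(spec.seed)
    is_shock = bool(rng.random() < spec.shock_fraction)
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    tj = t - spec.jet_onset

    if is_shock:
        env = (tj >= 0.0).astype(float)
    else:
        env = np.clip(tj / spec.ramp_duration, 0.0, 1.0)

    f_rip, a_rip = spec.ripple
    decay = (spec.jet_peak - spec.quasi_static) * np.exp(
        -np.maximum(tj, 0.0) / spec.jet_decay_tau)
    ripple = 1.0 + a_rip * np.sin(2.0 * np.pi * f_rip * np.maximum(tj, 0.0))
    rev = _reverb(t, spec)
    stag = _precursor(t, spec) + env * (decay * ripple + spec.quasi_static + rev)

    # static channel: slow pressurization + bounded fluctuation + one
    # guaranteed partial-vacuum dip as the ring vortex passes
    tau_s = 3e-3
    fluct_amp = min(4e3, 0.2 * spec.static_fluctuation_bound)
    fluct = fluct_amp * np.exp(-np.maximum(tj, 0.0) / 6e-3) \
        * np.sin(2.0 * np.pi * 700.0 * np.maximum(tj, 0.0))
    skel = env * (spec.quasi_static * (1.0 - np.exp(-np.maximum(tj, 0.0) / tau_s))
                  + fluct + 0.5 * rev)
    t_dip = spec.jet_onset + 1.2e-3
    if spec.vacuum_dip_depth > 0:
        at_dip = float(np.interp(t_dip, t, skel))
        dip_amp = spec.vacuum_dip_depth + max(at_dip, 0.0)
        skel = skel - dip_amp * np.exp(-(((t - t_dip) / 4e-4) ** 2))
    static = skel

    driver = spec.quasi_static + (spec.jet_peak - spec.quasi_static) \
        * np.exp(-t / (1.6 * spec.jet_decay_tau))

    out = {}
    for name, skeleton, role in (
            ("stagnation", stag, TraceRole.stagnation),
            ("static", static, TraceRole.static),
            ("driver", driver, TraceRole.driver)):
        samples = skeleton + spec.drift_rate * t
        if spec.noise_sd > 0:
            samples = samples + rng.normal(0.0, spec.noise_sd, t.size)
        out[name] = PressureTrace(channel_id=name, role=role,
                                  samples=samples, sample_rate=sample_rate)
    return out


def gen_blast_record(w: FriedlanderWave, sample_rate: float,
                     c: GasConstants = AIR,
                     dyn_duration_factor: float = 1.5,
                     dyn_decay_factor: float = 3.0) -> tuple:
    """Free-field blast pair: static Friedlander + dynamic-pressure channel.

    The dynamic channel peaks at the Rankine-Hugoniot partition value
    ``peak_dynamic_pressure(dp_peak)`` and uses a Friedlander-like shape
    with a larger decay exponent (more abrupt early decay) and a longer
    positive phase (``dyn_duration_factor * t_pos``), mirroring how blast
    wind differs from the static overpressure profile.
    """
    if sample_rate < 10.0 / w.t_pos:
        raise ValueError("sample_rate must resolve the positive phase "
                         "(at least 10 samples)")
    t_pos_d = dyn_duration_factor * w.t_pos
    t_end = 2.5 * max(w.t_pos, t_pos_d)
    t = np.arange(0.0, t_end, 1.0 / sample_rate)
    static = friedlander_pressure(t, w)
    q_peak = peak_dynamic_pressure(w.dp_peak, c)
    s = t / t_pos_d
    dynamic = q_peak * (1.0 - s) * np.exp(-dyn_decay_factor * w.b * s)
    return (
        PressureTrace(channel_id="blast_static", role=TraceRole.static,
                      samples=static, sample_rate=sample_rate),
        PressureTrace(channel_id="blast_dynamic", role=TraceRole.static,
                      samples=dynamic, sample_rate=sample_rate),
    )


def gen_track(true_motion: TrackRecord, frame_rate: float,
              pixel_noise: float, seed: int) -> TrackRecord:
    """Camera-style discretization of a true displacement history.

    Resamples the motion at ``frame_rate`` (which must not exceed the
    native sampling of ``true_motion``) and adds i.i.d. Gaussian position
    noise of standard deviation ``pixel_noise`` (m).
    """
    if frame_rate > true_motion.frame_rate:
        raise ValueError("frame_rate exceeds native sampling of the track")
    rng = np.random.default_rng(seed)
    t0, t1 = true_motion.times[0], true_motion.times[-1]
    t = np.arange(t0, t1 + 0.5 / frame_rate, 1.0 / frame_rate)
    t = t[t <= t1]
    x = np.interp(t, true_motion.times, true_motion.positions)
    if pixel_noise > 0:
        x = x + rng.normal(0.0, pixel_noise, t.size)
    return TrackRecord(times=t, positions=x, frame_rate=frame_rate)
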