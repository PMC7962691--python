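"""Pitot-static flow reduction.

A Pitot-static probe measures stagnation (total) pressure at its tip and
static ("side-on") pressure at its side port.  This module converts such
pairs into the flow quantities of interest: the Bernoulli dynamic pressure
q = p_stag - p_static, the Mach number, and the flow velocity.

Two inversion branches are implemented.  Subsonic flow uses the isentropic
Pitot relation

    p_stag / p_static = (1 + (gamma-1)/2 M^2)^(gamma/(gamma-1))

whose gamma = 1.4 value at the sonic point is 1.892929.  When the implied
Mach number exceeds 1 a detached bow shock stands ahead of the probe tip
and the Rayleigh-Pitot formula applies instead (measured stagnation
pressure is the post-normal-shock total pressure).  The two branches meet
continuously at M = 1.

Velocity recovery needs a temperature: the reduction assumes a known total
temperature ``T_ref`` (adiabatic flow from a reservoir at T_ref), so the
local static temperature is T_ref / (1 + (gamma-1)/2 M^2) -- exact in both
branches because total temperature is conserved across a shock.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .gas_core import AIR, GasConstants, sound_speed

__all__ = [
    "FlowRegime",
    "FlowPoint",
    "dynamic_pressure_bernoulli",
    "pitot_ratio",
    "mach_from_pitot",
    "reduce_trace_pair",
]


class FlowRegime(str, enum.Enum):
    incompressible = "incompressible"
    subsonic = "subsonic"
    supersonic = "supersonic"


#: Mach number below which the flow is labelled incompressible (q errors
#: from compressibility are under ~1%).
_INCOMPRESSIBLE_MACH = 0.2


@dataclass(frozen=True)
class FlowPoint:
    """A reduced (static, stagnation) pressure pair.

    ``q_dyn`` follows the Bernoulli convention of the apparatus analysis:
    the raw difference p_stag - p_static.  ``mach`` and ``velocity`` come
    from the compressible inversion.
    """

    p_static: float
    p_stag: float
    T_ref: float
    mach: float
    velocity: float
    q_dyn: float
    regime: FlowRegime

    def __post_init__(self) -> None:
        if self.p_stag < self.p_static:
            raise ValueError("stagnation pressure below static pressure")
        if self.mach < 0 or self.q_dyn < 0:
            raise ValueError("mach and q_dyn must be non-negative")
        if (self.regime is FlowRegime.supersonic) != (self.mach > 1.0):
            raise ValueError("regime inconsistent with mach number")


def dynamic_pressure_bernoulli(p_stag: float, p_static: float) -> float:
    """q = p_stag - p_static (Bernoulli partition of stagnation pressure)."""
    if p_stag < p_static:
        raise ValueError(
            f"stagnation channel ({p_stag!r} Pa) below static channel "
            f"({p_static!r} Pa): inverted pair"
        )
    return p_stag - p_static


def pitot_ratio(M, c: GasConstants = AIR):
    """Forward model: stagnation/static pressure ratio measured by a Pitot
    probe in flow of Mach M.  Isentropic for M <= 1, Rayleigh-Pitot above.
    Accepts arrays.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("Mach number must be non-negative")
    g = c.gamma
    m2 = M * M
    iso = (1.0 + 0.5 * (g - 1.0) * m2) ** (g / (g - 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        ray = ((0.5 * (g + 1.0) * m2) ** (g / (g - 1.0))
               * ((g + 1.0) / (2.0 * g * m2 - (g - 1.0))) ** (1.0 / (g - 1.0)))
    out = np.where(m2 > 1.0, ray, iso)
    return float(out) if out.ndim == 0 else out


def _mach_subsonic(ratio, c: GasConstants):
    g = c.gamma
    return np.sqrt(2.0 / (g - 1.0) * (np.asarray(ratio) ** ((g - 1.0) / g) - 1.0))


def _mach_supersonic(ratio: float, c: GasConstants) -> float:
    f = lambda M: pitot_ratio(M, c) - ratio
    try:
        return brentq(f, 1.0, 50.0, xtol=1e-13, rtol=1e-15)
    except ValueError as exc:  # pragma: no cover - out-of-bracket guard
        raise ValueError(
            f"Rayleigh-Pitot inversion failed for ratio {ratio!r}: {exc}"
        ) from exc


def mach_from_pitot(p_stag: float, p_static: float,
                    c: GasConstants = AIR, T_ref: float | None = None) -> FlowPoint:
    """Reduce one (stagnation, static) pressure pair to a FlowPoint.

    Inverts the isentropic Pitot relation; if the implied Mach number
    exceeds 1 the Rayleigh-Pitot branch is used instead.  ``T_ref`` is the
    total temperature of the flow (defaults to the ambient of ``c``).
    """
    if not (p_stag >= p_static > 0):
        raise ValueError("require p_stag >= p_static > 0")
    T_ref = c.T_amb if T_ref is None else T_ref
    ratio = p_stag / p_static
    g = c.gamma
    sonic_ratio = (0.5 * (g + 1.0)) ** (g / (g - 1.0))
    if ratio <= sonic_ratio:
        M = float(_mach_subsonic(ratio, c))
    else:
        M = _mach_supersonic(ratio, c)
    T_static = T_ref / (1.0 + 0.5 * (g - 1.0) * M * M)
    velocity = M * sound_speed(T_static, c)
    if M > 1.0:
        regime = FlowRegime.supersonic
    elif M > _INCOMPRESSIBLE_MACH:
        regime = FlowRegime.subsonic
    else:
        regime = FlowRegime.incompressible
    return FlowPoint(p_static=p_static, p_stag=p_stag, T_ref=T_ref,
                     mach=M, velocity=velocity,
                     q_dyn=p_stag - p_static, regime=regime)


def reduce_trace_pair(stag, stat, c: GasConstants = AIR,
                      T_ref: float | None = None):
    """Reduce a (stagnation, static) trace pair sample-by-sample.

    Parameters
    ----------
    stag, stat : PressureTrace
        Gauge-pressure traces of roles ``stagnation`` and ``static`` with
        identical sampling rate and overlapping time windows.

    Returns
    -------
    pandas.DataFrame
        Columns ``time_s, p_static, p_stag, q_dyn, mach, velocity, regime,
        clamped``.  Samples where the stagnation channel reads below the
        static channel (sensor noise) are clamped to q = 0 and flagged in
        ``clamped`` rather than dropped.
    """
    import pandas as pd

    if stag.sample_rate != stat.sample_rate:
        raise ValueError(
            f"mismatched sampling: stagnation {stag.sample_rate} Hz vs "
            f"static {stat.sample_rate} Hz"
        )
    t0 = max(stag.t0, stat.t0)
    t1 = min(stag.end_time, stat.end_time)
    if t1 <= t0:
        raise ValueError("trace time windows do not overlap")
    T_ref = c.T_amb if T_ref is None else T_ref

    sl_a = stag.window_slice(t0, t1)
    sl_b = stat.window_slice(t0, t1)
    n = min(sl_a.stop - sl_a.start, sl_b.stop - sl_b.start)
    p_stag = stag.samples[sl_a.start:sl_a.start + n] + c.p_amb
    p_stat = stat.samples[sl_b.start:sl_b.start + n] + c.p_amb
    times = stag.times[sl_a.start:sl_a.start + n]

    clamped = p_stag < p_stat
    p_stag_eff = np.where(clamped, p_stat, p_stag)
    ratio = p_stag_eff / p_stat
    g = c.gamma
    sonic_ratio = (0.5 * (g + 1.0)) ** (g / (g - 1.0))

    mach = np.asarray(_mach_subsonic(np.minimum(ratio, sonic_ratio), c))
    sup = ratio > sonic_ratio
    for i in np.flatnonzero(sup):
        mach[i] = _mach_supersonic(float(ratio[i]), c)
    T_static = T_ref / (1.0 + 0.5 * (g - 1.0) * mach ** 2)
    velocity = mach * sound_speed(T_static, c)
    q = np.where(clamped, 0.0, p_stag - p_stat)

    regime = np.where(mach > 1.0, FlowRegime.supersonic.value,
                      np.where(mach > _INCOMPRESSIBLE_MACH,
                               FlowRegime.subsonic.value,
                               FlowRegime.incompressible.value))
    return pd.DataFrame({
        "time_s": times,
        "p_static": p_stat,
        "p_stag": p_stag_eff,
        "q_dyn": q,
        "mach": mach,
        "velocity": velocity,
        "regime": regime,
        "clamped": clamped,
    })
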