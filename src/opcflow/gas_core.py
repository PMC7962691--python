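"""Closed-form ideal-gas, shock, isentropic and blast-wave relations.

This module is the computational kernel shared by the chamber simulation,
the Pitot-static reduction and the trace diagnostics.  Everything here is a
pure function of an ideal diatomic gas state: no file I/O, all quantities in
SI units, pressures *absolute* unless a name says ``gauge`` or
``overpressure``.

The blast-side relations describe a free-field blast wave: a shock front
carrying a peak static overpressure ``dp_s`` followed by a decaying profile
(the Friedlander waveform), with the "blast wind" carrying the peak dynamic
pressure ``q``.  For a perfect gas with gamma = 1.4 the Rankine-Hugoniot
jump conditions give the standard partition

    q = (5/2) * dp_s**2 / (7 * p_amb + dp_s)

which is what :func:`peak_dynamic_pressure` evaluates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GasConstants",
    "GasState",
    "FriedlanderWave",
    "AIR",
    "sound_speed",
    "peak_dynamic_pressure",
    "friedlander_pressure",
    "friedlander_impulse",
    "shock_mach_from_overpressure",
    "normal_shock_state",
    "isentropic_temperature",
    "tnt_equivalent_mass",
    "PSI_TO_PA",
]

#: Conversion factor, exact to the definition of the psi.
PSI_TO_PA = 6894.757


@dataclass(frozen=True)
class GasConstants:
    """Thermodynamic constants of the working gas and the ambient reference.

    Parameters
    ----------
    gamma : float
        Ratio of specific heats (1.4 for diatomic air).
    R_air : float
        Specific gas constant, J/(kg K).
    p_amb : float
        Ambient absolute pressure, Pa.
    T_amb : float
        Ambient temperature, K.
    e_TNT : float
        TNT specific energy, J/kg, used by :func:`tnt_equivalent_mass`.
    """

    gamma: float = 1.4
    R_air: float = 287.05
    p_amb: float = 101_325.0
    T_amb: float = 293.15
    e_TNT: float = 4.184e6

    def __post_init__(self) -> None:
        if self.gamma <= 1.0:
            raise ValueError(f"gamma must exceed 1, got {self.gamma}")
        for name in ("R_air", "p_amb", "T_amb", "e_TNT"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")

    @property
    def cp(self) -> float:
        """Specific heat at constant pressure, J/(kg K)."""
        return self.gamma * self.R_air / (self.gamma - 1.0)

    @property
    def rho_amb(self) -> float:
        """Ambient density from the ideal-gas law, kg/m^3."""
        return self.p_amb / (self.R_air * self.T_amb)


#: Default laboratory air.
AIR = GasConstants()


@dataclass(frozen=True)
class GasState:
    """Local thermodynamic and kinematic state of the gas.

    ``p`` absolute static pressure (Pa), ``rho`` density (kg/m^3), ``T``
    temperature (K), ``u`` flow velocity (m/s).  The ideal-gas closure
    ``p = rho * R_air * T`` must hold; it is checked on construction against
    the gas constants supplied via ``constants``.
    """

    p: float
    rho: float
    T: float
    u: float = 0.0
    constants: GasConstants = field(default=AIR, repr=False)

    def __post_init__(self) -> None:
        if self.p <= 0 or self.rho <= 0 or self.T <= 0:
            raise ValueError("p, rho and T must be positive")
        closure = self.rho * self.constants.R_air * self.T
        if abs(closure - self.p) > 1e-9 * self.p:
            raise ValueError(
                f"ideal-gas closure violated: p={self.p!r} but rho*R*T={closure!r}"
            )

    @classmethod
    def from_pT(cls, p: float, T: float, u: float = 0.0,
                constants: GasConstants = AIR) -> "GasState":
        """Build a state from pressure and temperature, closing the density."""
        return cls(p=p, rho=p / (constants.R_air * T), T=T, u=u,
                   constants=constants)

    @property
    def sound_speed(self) -> float:
        return sound_speed(self.T, self.constants)

    @property
    def mach(self) -> float:
        return abs(self.u) / self.sound_speed

    @property
    def dynamic_pressure(self) -> float:
        """q = rho u^2 / 2, Pa."""
        return 0.5 * self.rho * self.u * self.u


@dataclass(frozen=True)
class FriedlanderWave:
    """Canonical free-field blast profile.

    Instantaneous rise to ``dp_peak`` followed by the modified-exponential
    decay ``dp_peak * (1 - t/t_pos) * exp(-b t / t_pos)``: zero crossing at
    the positive-phase duration ``t_pos``, then an under-pressure phase for
    ``b > 0`` relaxing back toward ambient.
    """

    dp_peak: float
    t_pos: float
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.dp_peak <= 0:
            raise ValueError("dp_peak must be positive")
        if self.t_pos <= 0:
            raise ValueError("t_pos must be positive")
        if self.b < 0:
            raise ValueError("b must be non-negative")


def sound_speed(T, c: GasConstants = AIR):
    """Speed of sound a = sqrt(gamma R T), m/s.  Accepts arrays."""
    import numpy as np

    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    out = np.sqrt(c.gamma * c.R_air * T)
    return float(out) if out.ndim == 0 else out


def peak_dynamic_pressure(dp_s: float, c: GasConstants = AIR) -> float:
    """Peak dynamic pressure behind a shock of peak static overpressure dp_s.

    Evaluates the gamma = 1.4 Rankine-Hugoniot partition
    ``q = (5/2) dp_s^2 / (7 p_amb + dp_s)``.  For weak blasts
    (dp_s < ~10 kPa) q is negligible; near dp_s ~ 5 atm the static and
    dynamic peaks are about equal.

    The general-gamma form is ``q = dp_s^2 / (2 gamma p_amb +
    (gamma - 1) dp_s)``; with gamma = 1.4 the coefficients reduce to the
    5/2 and 7 above.
    """
    if dp_s < 0:
        raise ValueError("overpressure must be non-negative")
    g = c.gamma
    return dp_s * dp_s / (2.0 * g * c.p_amb + (g - 1.0) * dp_s)


def _friedlander_scalar(t: float, w: FriedlanderWave) -> float:
    if t < 0:
        raise ValueError("time must be non-negative")
    x = t / w.t_pos
    return w.dp_peak * (1.0 - x) * math.exp(-w.b * x)


def friedlander_pressure(t, w: FriedlanderWave):
    """Overpressure of a Friedlander wave at time(s) t >= 0 after shock arrival."""
    import numpy as np

    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    x = t / w.t_pos
    out = w.dp_peak * (1.0 - x) * np.exp(-w.b * x)
    return float(out) if out.ndim == 0 else out


def friedlander_impulse(w: FriedlanderWave) -> float:
    """Closed-form positive-phase impulse, integral of p over [0, t_pos], Pa s.

    For b = 0 this is the triangle area dp_peak * t_pos / 2; for b > 0,
    dp_peak * t_pos * [ (1 - e^-b)/b - (1 - (1+b) e^-b)/b^2 ].
    """
    b = w.b
    if b == 0.0:
        return 0.5 * w.dp_peak * w.t_pos
    eb = math.exp(-b)
    integral = (1.0 - eb) / b - (1.0 - (1.0 + b) * eb) / (b * b)
    return w.dp_peak * w.t_pos * integral


def shock_mach_from_overpressure(dp_s: float, c: GasConstants = AIR) -> float:
    """Shock Mach number of a front with static overpressure dp_s.

    From the Rankine-Hugoniot pressure jump
    ``p2/p1 = 1 + 2 gamma (Ms^2 - 1) / (gamma + 1)`` inverted for Ms:
    ``Ms = sqrt(1 + (gamma+1)/(2 gamma) * dp_s/p_amb)``.  Ms -> 1 in the
    acoustic limit.
    """
    if dp_s < 0:
        raise ValueError("overpressure must be non-negative")
    g = c.gamma
    return math.sqrt(1.0 + (g + 1.0) / (2.0 * g) * dp_s / c.p_amb)


def normal_shock_state(Ms: float, c: GasConstants = AIR) -> GasState:
    """Post-shock gas state behind a normal shock of Mach Ms moving into
    ambient air at rest (laboratory frame).

    Returns the full Rankine-Hugoniot jump: pressure, density, temperature
    and the induced particle velocity u2.  Used as the cross-check that the
    closed-form :func:`peak_dynamic_pressure` equals rho2 u2^2 / 2.
    """
    if Ms < 1.0:
        raise ValueError("shock Mach number must be >= 1")
    g = c.gamma
    p2 = c.p_amb * (1.0 + 2.0 * g / (g + 1.0) * (Ms * Ms - 1.0))
    rho2 = c.rho_amb * (g + 1.0) * Ms * Ms / ((g - 1.0) * Ms * Ms + 2.0)
    T2 = p2 / (rho2 * c.R_air)
    a1 = sound_speed(c.T_amb, c)
    u2 = 2.0 * a1 / (g + 1.0) * (Ms - 1.0 / Ms)
    return GasState(p=p2, rho=rho2, T=T2, u=u2, constants=c)


def isentropic_temperature(p2: float, p1: float, T1: float,
                           c: GasConstants = AIR) -> float:
    """Temperature after an isentropic pressure change p1 -> p2.

    T2 = T1 (p2/p1)^((gamma-1)/gamma).  Expanding the 239 kPa driver gas to
    sub-ambient pressure cools it to around -60 degC, which is why the
    vented jet is cold and dense.
    """
    if p1 <= 0 or p2 <= 0 or T1 <= 0:
        raise ValueError("pressures and temperature must be positive")
    g = c.gamma
    return T1 * (p2 / p1) ** ((g - 1.0) / g)


def tnt_equivalent_mass(dp_gauge: float, V: float, c: GasConstants = AIR,
                        yield_factor: float = 1.0) -> float:
    """TNT-equivalent mass of a compressed-gas volume.

    The stored compression energy of gas at gauge pressure ``dp_gauge`` in
    volume ``V`` is ``dp_gauge V / (gamma - 1)``; dividing by the TNT
    specific energy gives an ideal equivalent mass.  ``yield_factor``
    (default 1) scales for the fact that compressed-gas bursts couple less
    efficiently into blast than a detonation.
    """
    if dp_gauge < 0:
        raise ValueError("gauge pressure must be non-negative")
    if V <= 0:
        raise ValueError("volume must be positive")
    return yield_factor * dp_gauge * V / ((c.gamma - 1.0) * c.e_TNT)
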