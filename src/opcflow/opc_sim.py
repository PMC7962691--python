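"""Simulation of the overpressure-chamber venting event.

The apparatus is a closed steel vessel (0.6 m diameter, 1.8 m long) split
by a partition into a short pressurized Driver section and a long Test
section, connected by a 14 cm aperture that is sealed by a frangible Mylar
diaphragm.  When the diaphragm bursts (nominally at 138 kPa gauge) three
things happen, and each has a model here at the fidelity a desk-scale
study supports:

* the pressurized gas in the diaphragm bulge releases a weak spherically
  expanding precursor wavelet -- :func:`solve_spherical_burst`;
* the driver blows down through the aperture as a cold collimated jet that
  decays over tens of milliseconds -- :func:`solve_quasi1d`, a quasi-1D
  Euler model with axially varying cross-section;
* both compartments equilibrate to a common quasi-static pressure a little
  above ambient, approached in stages timed by a longitudinal compression
  wave reverberating along the test section -- visible in the simulated
  probe traces and cross-checked against the two-volume orifice-discharge
  model :func:`lumped_blowdown`.

The quasi-1D surrogate cannot represent the ring vortex that the full
axisymmetric CFD resolves (and with it the >450 m/s local velocities); the
jet column is instead modelled as a duct of aperture cross-section
extending past the specimen station before relaxing to the vessel bore.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ._euler import EulerSolver, SolverError
from .gas_core import AIR, GasConstants
from .trace_dx import PressureTrace, TraceRole

__all__ = [
    "ChamberGeometry",
    "BurstModel",
    "FieldHistory",
    "SolverError",
    "lumped_blowdown",
    "solve_quasi1d",
    "solve_spherical_burst",
    "jet_front_speed",
    "jet_decay_duration",
]


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber geometry and probe layout.

    The driver length is not part of the published apparatus description;
    the 0.20 m default is calibrated so that the two-volume equilibrium of
    a 138 kPa burst lands at the observed ~15 kPa quasi-static level.

    ``jet_column_length`` / ``expansion_length`` parameterize the quasi-1D
    surrogate of the collimated jet: downstream of the aperture the duct
    keeps the aperture cross-section for ``jet_column_length`` (covering
    the specimen station, which sits within one aperture diameter of the
    partition and hence inside the potential core of the real jet) and then
    relaxes to the vessel bore over ``expansion_length``.
    """

    diameter: float = 0.6
    total_length: float = 1.8
    driver_length: float = 0.20
    aperture_diameter: float = 0.14
    specimen_standoff: float = 0.127
    contraction_length: float = 0.04
    jet_column_length: float = 0.15
    expansion_length: float = 0.10
    probe_stations: tuple = ()

    def __post_init__(self) -> None:
        if not 0 < self.driver_length < self.total_length:
            raise ValueError("require 0 < driver_length < total_length")
        if not 0 < self.aperture_diameter < self.diameter:
            raise ValueError("aperture must be smaller than the vessel bore")
        if self.specimen_standoff <= 0:
            raise ValueError("specimen_standoff must be positive")
        if not self.probe_stations:
            object.__setattr__(self, "probe_stations", (
                (0.5 * self.driver_length, "driver"),
                (self.specimen_position, "specimen"),
                (self.total_length, "end_wall"),
            ))

    @property
    def bore_area(self) -> float:
        return 0.25 * math.pi * self.diameter ** 2

    @property
    def aperture_area(self) -> float:
        return 0.25 * math.pi * self.aperture_diameter ** 2

    @property
    def aperture_position(self) -> float:
        return self.driver_length

    @property
    def specimen_position(self) -> float:
        return self.driver_length + self.specimen_standoff

    def area(self, x):
        """Duct cross-section A(x) of the quasi-1D surrogate, m^2."""
        x = np.asarray(x, dtype=float)
        A_full = self.bore_area
        A_ap = self.aperture_area
        x1 = self.driver_length - self.contraction_length
        x2 = self.driver_length
        x3 = x2 + self.jet_column_length
        x4 = x3 + self.expansion_length

        out = np.full(x.shape, A_full)
        s = np.clip((x - x1) / (x2 - x1), 0.0, 1.0)
        contr = A_ap + (A_full - A_ap) * 0.5 * (1.0 + np.cos(math.pi * s))
        out = np.where((x >= x1) & (x < x3), np.where(x < x2, contr, A_ap), out)
        s2 = np.clip((x - x3) / (x4 - x3), 0.0, 1.0)
        expan = A_ap + (A_full - A_ap) * 0.5 * (1.0 - np.cos(math.pi * s2))
        out = np.where((x >= x3) & (x < x4), expan, out)
        return float(out) if out.ndim == 0 else out

    def volumes(self, n_quad: int = 20_000) -> tuple:
        """(driver volume, test-section volume) of the surrogate duct, m^3."""
        x = np.linspace(0.0, self.total_length, n_quad)
        a = self.area(x)
        split = x <= self.driver_length
        v_d = float(np.trapezoid(a[split], x[split]))
        v_t = float(np.trapezoid(a[~split], x[~split]))
        return v_d, v_t


@dataclass(frozen=True)
class BurstModel:
    """Diaphragm burst conditions and opening law.

    ``petal_duration`` is the time for the Mylar petals to fold clear
    (~0.3 ms observed); with ``opening_profile="linear_ramp"`` the open
    area fraction grows linearly over that time.  ``shock_fraction`` is the
    observed probability that the non-ideal rupture launches a true shock
    front rather than a ramped jet onset; it parameterizes the synthetic
    record generator, not the deterministic solver.
    """

    burst_gauge_pressure: float = 138e3
    petal_duration: float = 3e-4
    bulge_radius: float = 0.07
    opening_profile: str = "linear_ramp"
    shock_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.burst_gauge_pressure <= 0:
            raise ValueError("burst_gauge_pressure must be positive")
        if self.petal_duration < 0:
            raise ValueError("petal_duration must be non-negative")
        if not 0.0 <= self.shock_fraction <= 1.0:
            raise ValueError("shock_fraction must lie in [0, 1]")
        if self.opening_profile not in ("instantaneous", "linear_ramp"):
            raise ValueError(f"unknown opening_profile {self.opening_profile!r}")

    def open_fraction(self, t: float) -> float:
        if self.opening_profile == "instantaneous" or self.petal_duration == 0:
            return 1.0
        return min(t / self.petal_duration, 1.0)


@dataclass
class FieldHistory:
    """Full result of a quasi-1D chamber run.

    ``times`` and the 2-D arrays are coarse field snapshots;
    ``station_records`` holds per-step primitive histories at each probe
    station (from which the uniformly resampled ``probe_traces`` derive);
    the front-tracking and minimum-temperature series are also per-step.
    """

    times: np.ndarray
    cell_centers: np.ndarray
    rho: np.ndarray
    u: np.ndarray
    p: np.ndarray
    T: np.ndarray
    scalar: np.ndarray
    probe_traces: dict
    station_records: dict
    fine_times: np.ndarray
    front_positions: np.ndarray
    min_T_downstream: np.ndarray
    mass_series: np.ndarray
    energy_series: np.ndarray
    geometry: ChamberGeometry
    burst: BurstModel
    constants: GasConstants = field(default=AIR)

    @property
    def aperture_position(self) -> float:
        return self.geometry.aperture_position

    @property
    def specimen_position(self) -> float:
        return self.geometry.specimen_position

    def station_flow_history(self, name: str = "specimen"):
        """(t, rho, u) per-step history at a named probe station."""
        rec = self.station_records[name]
        return rec["t"], rec["rho"], rec["u"]

    def min_jet_temperature(self, t_max: float = 10e-3,
                            region: str = "column") -> float:
        """Minimum gas temperature in the vented jet up to ``t_max``, K.

        ``region="column"`` (default) takes the minimum over the modelled
        jet column, aperture plane to column end -- the part of the duct
        that represents the physical jet.  The downstream relaxation cone
        is a numerical device of the quasi-1D surrogate (the real jet
        boundary is a free shear layer, not a duct wall) and supersonic
        over-expansion there is not interpreted; ``region="downstream"``
        includes it anyway.
        """
        if region == "downstream":
            mask = self.fine_times <= t_max
            return float(np.min(self.min_T_downstream[mask]))
        if region != "column":
            raise ValueError(f"unknown region {region!r}")
        g = self.geometry
        tmask = self.times <= t_max
        cmask = (self.cell_centers >= g.aperture_position) & \
            (self.cell_centers <= g.aperture_position + g.jet_column_length)
        return float(np.min(self.T[np.ix_(tmask, cmask)]))

    def mean_chamber_pressure(self, window: tuple) -> float:
        """Volume-averaged absolute pressure over a time window, Pa.

        This is the quantity the lumped two-volume model predicts at late
        time; point probes superpose the standing reverberation wave on it.
        """
        tmask = (self.times >= window[0]) & (self.times <= window[1])
        if not np.any(tmask):
            raise ValueError("window outside snapshot range")
        V = self.geometry.area(self.cell_centers) * np.gradient(
            self.cell_centers)
        return float(np.mean(self.p[tmask] @ V) / np.sum(V))

    def conservation_drift(self) -> tuple:
        """(relative mass drift, relative energy drift) over the run."""
        m = self.mass_series
        e = self.energy_series
        return (float(np.max(np.abs(m - m[0])) / m[0]),
                float(np.max(np.abs(e - e[0])) / e[0]))


def lumped_blowdown(geom: ChamberGeometry, burst: BurstModel,
                    t_end: float, constants: GasConstants = AIR,
                    sample_rate: float = 1e5):
    """Two-volume orifice-discharge model of the driver blowdown.

    Adiabatic volumes exchanging mass through an isentropic-nozzle orifice
    of the aperture area (choked while the pressure ratio exceeds the
    critical ~1.893), with the open area following the diaphragm petal
    ramp.  Receiving-volume kinetic energy is assumed dissipated, so total
    internal energy is conserved and both volumes converge to the
    energy-weighted equilibrium pressure
    (p_d V_d + p_t V_t) / (V_d + V_t).

    Returns
    -------
    (PressureTrace, float)
        The driver gauge-pressure decay trace and the quasi-static gauge
        level both volumes converge to.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    A_ap = geom.aperture_area
    if A_ap <= 0:
        raise ValueError("zero aperture area: degenerate geometry, no flow")
    g = constants.gamma
    R = constants.R_air
    cv = R / (g - 1.0)
    cp = constants.cp
    V_d, V_t = geom.volumes()
    p_d0 = constants.p_amb + burst.burst_gauge_pressure
    T0 = constants.T_amb
    y0 = [p_d0 * V_d / (R * T0),            # driver mass
          p_d0 * V_d / (g - 1.0),           # driver internal energy
          constants.p_amb * V_t / (R * T0),
          constants.p_amb * V_t / (g - 1.0)]
    crit = (2.0 / (g + 1.0)) ** (g / (g - 1.0))

    def mdot(p_up, T_up, p_down, area):
        if area <= 0 or p_up <= p_down:
            return 0.0
        pr = p_down / p_up
        if pr <= crit:
            return (area * p_up * math.sqrt(g / (R * T_up))
                    * (2.0 / (g + 1.0)) ** ((g + 1.0) / (2.0 * (g - 1.0))))
        term = pr ** (2.0 / g) - pr ** ((g + 1.0) / g)
        return area * p_up * math.sqrt(2.0 * g / ((g - 1.0) * R * T_up) * term)

    def rhs(t, y):
        m_d, E_d, m_t, E_t = y
        T_d = E_d / (m_d * cv)
        T_t = E_t / (m_t * cv)
        p_d = m_d * R * T_d / V_d
        p_t = m_t * R * T_t / V_t
        area = A_ap * burst.open_fraction(t)
        if p_d >= p_t:
            f = mdot(p_d, T_d, p_t, area)
            return [-f, -f * cp * T_d, f, f * cp * T_d]
        f = mdot(p_t, T_t, p_d, area)
        return [f, f * cp * T_t, -f, -f * cp * T_t]

    times = np.arange(0.0, t_end + 0.5 / sample_rate, 1.0 / sample_rate)
    times = times[times <= t_end]
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="RK45", t_eval=times,
                    rtol=1e-8, atol=1e-10, max_step=t_end / 50)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"blowdown integration failed: {sol.message}")
    m_d, E_d = sol.y[0], sol.y[1]
    p_driver = (g - 1.0) * E_d / V_d
    qs_gauge = (g - 1.0) * (sol.y[1][-1] + sol.y[3][-1]) / (V_d + V_t) \
        - constants.p_amb
    trace = PressureTrace(channel_id="driver_lumped", role=TraceRole.driver,
                          samples=p_driver - constants.p_amb,
                          sample_rate=sample_rate, t0=0.0)
    return trace, float(qs_gauge)


def _stagnation_gauge(p, rho, u, c: GasConstants):
    """Pitot stagnation gauge pressure from local static state (vectorized)."""
    from .flow_reduction import pitot_ratio

    a = np.sqrt(c.gamma * p / rho)
    M = np.abs(u) / a
    return p * pitot_ratio(M, c) - c.p_amb


def solve_quasi1d(geom: ChamberGeometry, burst: BurstModel,
                  t_end: float = 60e-3, n_cells: int = 720,
                  cfl: float = 0.5, constants: GasConstants = AIR,
                  snapshot_dt: float = 1e-4,
                  trace_rate: float = 8e5) -> FieldHistory:
    """Quasi-1D Euler simulation of the venting event.

    The closed vessel is discretized on ``n_cells`` uniform cells with the
    duct area of :meth:`ChamberGeometry.area`; the diaphragm is a partially
    open face whose open fraction follows the burst opening law.  Driver
    gas carries a passive scalar (1 in the driver, 0 in the test section)
    whose 0.5 level tracks the vented-gas front.
    """
    if n_cells < 100:
        raise ValueError("n_cells must be at least 100")
    if not 0 < cfl <= 1:
        raise ValueError("require 0 < cfl <= 1")
    L = geom.total_length
    x_faces = np.linspace(0.0, L, n_cells + 1)
    dx = L / n_cells
    jd = int(round(geom.driver_length / dx))
    area_faces = geom.area(x_faces)
    # the diaphragm face must sit in the throat
    area_faces[jd] = geom.aperture_area

    solver = EulerSolver(x_faces=x_faces, area_faces=area_faces,
                         gamma=constants.gamma, R=constants.R_air,
                         bc=("wall", "wall"), diaphragm_face=jd,
                         open_fraction=burst.open_fraction)
    xc = solver.x_centers
    driver_side = np.arange(n_cells) < jd
    p0 = np.where(driver_side, constants.p_amb + burst.burst_gauge_pressure,
                  constants.p_amb)
    rho0 = p0 / (constants.R_air * constants.T_amb)
    solver.set_state(rho0, 0.0, p0, scalar=driver_side.astype(float))

    stations = {}
    for x_st, name in geom.probe_stations:
        idx = int(np.clip(np.searchsorted(xc, x_st), 0, n_cells - 1))
        if idx > 0 and abs(xc[idx - 1] - x_st) < abs(xc[idx] - x_st):
            idx -= 1
        stations[name] = idx

    rec = {name: {"t": [], "p": [], "rho": [], "u": [], "T": []}
           for name in stations}
    fine_t, front_pos, min_T = [], [], []
    snaps = {"t": [], "rho": [], "u": [], "p": [], "T": [], "phi": [],
             "mass": [], "energy": []}
    next_snap = [0.0]
    down = slice(jd, None)

    def callback(s: EulerSolver) -> None:
        rho, u, p, phi = s.primitives()
        T = p / (rho * constants.R_air)
        fine_t.append(s.t)
        min_T.append(float(np.min(T[down])))
        beyond = np.flatnonzero(phi[down] >= 0.5)
        front_pos.append(xc[jd + beyond[-1]] if beyond.size else np.nan)
        for name, idx in stations.items():
            r = rec[name]
            r["t"].append(s.t)
            r["p"].append(p[idx])
            r["rho"].append(rho[idx])
            r["u"].append(u[idx])
            r["T"].append(T[idx])
        if s.t >= next_snap[0] - 1e-12:
            snaps["t"].append(s.t)
            snaps["rho"].append(rho.copy())
            snaps["u"].append(u.copy())
            snaps["p"].append(p.copy())
            snaps["T"].append(T.copy())
            snaps["phi"].append(phi.copy())
            snaps["mass"].append(s.total_mass())
            snaps["energy"].append(s.total_energy())
            next_snap[0] += snapshot_dt

    solver.run(t_end, cfl=cfl, callback=callback)

    for name in rec:
        for k in rec[name]:
            rec[name][k] = np.asarray(rec[name][k])

    t_uniform = np.arange(0.0, t_end, 1.0 / trace_rate)
    traces = {}
    for name, idx in stations.items():
        r = rec[name]
        p_gauge = np.interp(t_uniform, r["t"], r["p"] - constants.p_amb)
        role = TraceRole.driver if name == "driver" else TraceRole.static
        key = name if name == "driver" else f"{name}_static"
        traces[key] = PressureTrace(channel_id=key, role=role,
                                    samples=p_gauge, sample_rate=trace_rate)
        if name == "specimen":
            stag = _stagnation_gauge(r["p"], r["rho"], r["u"], constants)
            traces["specimen_stagnation"] = PressureTrace(
                channel_id="specimen_stagnation", role=TraceRole.stagnation,
                samples=np.interp(t_uniform, r["t"], stag),
                sample_rate=trace_rate)

    return FieldHistory(
        times=np.asarray(snaps["t"]), cell_centers=xc,
        rho=np.asarray(snaps["rho"]), u=np.asarray(snaps["u"]),
        p=np.asarray(snaps["p"]), T=np.asarray(snaps["T"]),
        scalar=np.asarray(snaps["phi"]),
        probe_traces=traces, station_records=rec,
        fine_times=np.asarray(fine_t),
        front_positions=np.asarray(front_pos),
        min_T_downstream=np.asarray(min_T),
        mass_series=np.asarray(snaps["mass"]),
        energy_series=np.asarray(snaps["energy"]),
        geometry=geom, burst=burst, constants=constants,
    )


def _spherical_run(burst: BurstModel, r_targets: Sequence[float],
                   t_end: float, constants: GasConstants,
                   n_cells: int, r_max: float, cfl: float,
                   opening: str = "instantaneous") -> dict:
    r0 = burst.bulge_radius
    faces = np.linspace(0.0, r_max, n_cells + 1)
    vols = np.diff(faces ** 3) / 3.0
    jd = int(round(r0 / (r_max / n_cells)))
    open_fn = None if opening == "instantaneous" else burst.open_fraction
    solver = EulerSolver(x_faces=faces, area_faces=faces ** 2,
                         gamma=constants.gamma, R=constants.R_air,
                         volumes=vols, bc=("wall", "transmissive"),
                         diaphragm_face=jd if open_fn else None,
                         open_fraction=open_fn)
    rc = solver.x_centers
    inside = np.arange(n_cells) < jd
    p_init = np.where(inside, constants.p_amb + burst.burst_gauge_pressure,
                      constants.p_amb)
    rho_init = p_init / (constants.R_air * constants.T_amb)
    solver.set_state(rho_init, 0.0, p_init)

    idxs = {}
    for r_t in r_targets:
        idxs[r_t] = int(np.argmin(np.abs(rc - r_t)))
    times, values = [], {r_t: [] for r_t in r_targets}

    def callback(s: EulerSolver) -> None:
        _, _, p, _ = s.primitives()
        times.append(s.t)
        for r_t, i in idxs.items():
            values[r_t].append(p[i] - constants.p_amb)

    solver.run(t_end, cfl=cfl, callback=callback)
    t = np.asarray(times)
    rate = 8e5
    t_uniform = np.arange(0.0, t_end, 1.0 / rate)
    out = {}
    for r_t in r_targets:
        out[r_t] = PressureTrace(
            channel_id=f"wavelet_r{r_t:.3f}", role=TraceRole.static,
            samples=np.interp(t_uniform, t, np.asarray(values[r_t])),
            sample_rate=rate)
    return out


def solve_spherical_burst(burst: BurstModel, r_target: float,
                          t_end: float = 2.0e-3,
                          constants: GasConstants = AIR,
                          n_cells: int = 1200, r_max: float = 0.6,
                          cfl: float = 0.45,
                          opening: str = "instantaneous") -> PressureTrace:
    """Precursor-wavelet model: burst of the pressurized diaphragm bulge.

    A sphere of radius ``bulge_radius`` at the burst pressure releases
    into ambient air; the 1-D spherically symmetric Euler equations are
    integrated and the static overpressure trace at radius ``r_target``
    returned (a hemispherical bulge on the partition wall is equivalent to
    a full sphere by image symmetry for on-axis observers).  The release
    is instantaneous by default: the bulge is the torn membrane's own gas
    pocket, already outboard of the aperture plane -- the petaling ramp
    throttles the driver flow behind it, which is the duct solver's
    diaphragm face, not the bulge surface.  Pass ``opening="ramp"`` to
    apply the burst opening law to the bulge surface instead.  The peak
    decays monotonically with range, steeper than 1/r in the near field.
    """
    if r_target <= burst.bulge_radius:
        raise ValueError(
            f"r_target {r_target} m lies inside the initial bulge "
            f"({burst.bulge_radius} m)")
    if r_target >= r_max:
        raise ValueError("r_target beyond the computational domain")
    return _spherical_run(burst, [r_target], t_end, constants,
                          n_cells, r_max, cfl, opening=opening)[r_target]


def jet_front_speed(h: FieldHistory, window: tuple | None = None) -> float:
    """Mean speed of the vented-gas front across an axial window, m/s.

    The front is the farthest cell downstream of the aperture where the
    advected driver-gas scalar exceeds 0.5.  Default window: aperture plane
    to specimen station.
    """
    if window is None:
        window = (h.aperture_position, h.specimen_position)
    x1, x2 = window
    if x2 <= x1:
        raise ValueError("window must be increasing")
    if x1 < h.aperture_position - 1e-9:
        raise ValueError("window must lie downstream of the aperture")
    ok = ~np.isnan(h.front_positions)
    if not np.any(ok):
        raise ValueError("vented-gas front never formed "
                         "(zero burst pressure or closed diaphragm?)")
    reached1 = ok & (h.front_positions >= x1)
    reached2 = ok & (h.front_positions >= x2)
    if not np.any(reached2):
        raise ValueError(f"front never reached x = {x2} m")
    if not np.any(reached1):
        raise ValueError(f"front never entered the window at x = {x1} m")
    t1 = h.fine_times[np.argmax(reached1)]
    t2 = h.fine_times[np.argmax(reached2)]
    if t2 <= t1:
        raise ValueError("window too narrow to resolve the front transit")
    return float((x2 - x1) / (t2 - t1))


def jet_decay_duration(h: FieldHistory, band: float | None = None,
                       station: str = "specimen",
                       envelope_window: float = 1e-3) -> float:
    """Time for the stagnation record to settle onto the quasi-static level.

    Defined as the first time after which the on-axis stagnation gauge
    pressure stays within ``band`` (default 10% of the burst gauge
    pressure) of the quasi-static asymptote (median of the final 20% of
    the record), in seconds.  The criterion is applied to the decay
    envelope -- the trace smoothed by an ``envelope_window`` boxcar --
    because the weakly-dissipative 1-D model overstates the impulsive
    reverberation spikes that ride on the decay; set
    ``envelope_window=0`` for the raw trace.
    """
    from dataclasses import replace

    from .trace_dx import settling_time

    trace = h.probe_traces[f"{station}_stagnation"]
    if band is None:
        band = 0.1 * h.burst.burst_gauge_pressure
    if envelope_window > 0:
        k = max(1, int(envelope_window * trace.sample_rate))
        smooth = np.convolve(trace.samples, np.ones(k) / k, mode="same")
        trace = replace(trace, samples=smooth)
    n_qs = max(2, int(0.2 * len(trace)))
    qs = float(np.median(trace.samples[-n_qs:]))
    return settling_time(trace, qs, band)
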