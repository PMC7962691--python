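"""Finite-volume core: quasi-1D compressible Euler equations.

One kernel serves both chamber geometries: a duct of axially varying
cross-section A(x) (the venting chamber) and spherical symmetry (the
precursor-wavelet burst, where A(r) = r^2 up to a constant).  The scheme is
a MUSCL-Hancock-style second-order method: minmod-limited linear
reconstruction of primitives, HLLC approximate Riemann fluxes, SSP-RK2 time
stepping, with the area variation entering through face areas, cell volumes
and the p dA/dx momentum source (well balanced: a uniform quiescent state
is an exact steady state).

A diaphragm is modelled as a partially open face: the open fraction phi(t)
scales the Riemann flux while the closed fraction contributes a wall
pressure to the momentum of each neighbour.  Mass and energy are conserved
to round-off for any phi, exactly as in a conservative scheme once the
face is fully open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["SolverError", "EulerSolver"]

_TINY = 1e-12


class SolverError(RuntimeError):
    """Raised when the solver state becomes non-physical (NaN or p,rho <= 0)."""

    def __init__(self, message: str, time: float | None = None,
                 cell: int | None = None):
        super().__init__(message)
        self.time = time
        self.cell = cell


def _minmod(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.where(np.abs(a) < np.abs(b), a, b)
    return np.where(a * b <= 0.0, 0.0, out)


def _hllc(rL, uL, pL, sL, rR, uR, pR, sR, gamma):
    """Vectorized HLLC flux for Euler + passive scalar.

    Returns (f_mass, f_mom, f_energy, f_scalar) at each face.  Wave-speed
    estimates follow Toro's PVRS pressure guess with shock-corrected
    acoustic speeds.
    """
    aL = np.sqrt(gamma * pL / rL)
    aR = np.sqrt(gamma * pR / rR)
    rbar = 0.5 * (rL + rR)
    abar = 0.5 * (aL + aR)
    p_est = np.maximum(0.5 * (pL + pR) - 0.5 * (uR - uL) * rbar * abar, _TINY)

    gfac = (gamma + 1.0) / (2.0 * gamma)
    qL = np.where(p_est > pL, np.sqrt(1.0 + gfac * (p_est / pL - 1.0)), 1.0)
    qR = np.where(p_est > pR, np.sqrt(1.0 + gfac * (p_est / pR - 1.0)), 1.0)
    SL = uL - aL * qL
    SR = uR + aR * qR

    dL = rL * (SL - uL)
    dR = rR * (SR - uR)
    SM = (pR - pL + uL * dL - uR * dR) / (dL - dR)

    EL = pL / (gamma - 1.0) + 0.5 * rL * uL * uL
    ER = pR / (gamma - 1.0) + 0.5 * rR * uR * uR

    fL = (rL * uL, rL * uL * uL + pL, uL * (EL + pL), rL * uL * sL)
    fR = (rR * uR, rR * uR * uR + pR, uR * (ER + pR), rR * uR * sR)

    # star-region conservative states
    cL = dL / (SL - SM)
    cR = dR / (SR - SM)
    p_starL = pL + dL * (SM - uL)
    UsL = (cL, cL * SM, cL * (EL / rL + (SM - uL) * (SM + pL / dL)), cL * sL)
    UsR = (cR, cR * SM, cR * (ER / rR + (SM - uR) * (SM + pR / dR)), cR * sR)
    ULc = (rL, rL * uL, EL, rL * sL)
    URc = (rR, rR * uR, ER, rR * sR)

    out = []
    for k in range(4):
        f_sL = fL[k] + SL * (UsL[k] - ULc[k])
        f_sR = fR[k] + SR * (UsR[k] - URc[k])
        f = np.where(SL >= 0.0, fL[k],
                     np.where(SM >= 0.0, f_sL,
                              np.where(SR > 0.0, f_sR, fR[k])))
        out.append(f)
    return out


@dataclass
class EulerSolver:
    """Quasi-1D Euler solver on a fixed grid.

    Parameters
    ----------
    x_faces : (n+1,) face coordinates, strictly increasing.
    area_faces : (n+1,) duct cross-section (or r^2 metric) at faces.
    volumes : (n,) cell volumes; by default the trapezoid of area_faces.
    gamma, R : gas properties.
    bc : pair of "wall" or "transmissive" boundary types.
    diaphragm_face : face index of a partially open diaphragm, or None.
    open_fraction : callable t -> fraction in [0, 1] for that face.
    """

    x_faces: np.ndarray
    area_faces: np.ndarray
    gamma: float = 1.4
    R: float = 287.05
    volumes: np.ndarray | None = None
    bc: tuple = ("wall", "wall")
    diaphragm_face: int | None = None
    open_fraction: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        self.x_faces = np.asarray(self.x_faces, dtype=float)
        self.area_faces = np.asarray(self.area_faces, dtype=float)
        n = self.x_faces.size - 1
        if n < 3:
            raise ValueError("need at least 3 cells")
        if np.any(np.diff(self.x_faces) <= 0):
            raise ValueError("x_faces must be strictly increasing")
        self.dx = np.diff(self.x_faces)
        self.x_centers = 0.5 * (self.x_faces[:-1] + self.x_faces[1:])
        if self.volumes is None:
            self.volumes = 0.5 * (self.area_faces[:-1]
                                  + self.area_faces[1:]) * self.dx
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.n = n
        self.t = 0.0
        self._U: np.ndarray | None = None

    # -- state ------------------------------------------------------------

    def set_state(self, rho, u, p, scalar=None) -> None:
        rho = np.broadcast_to(np.asarray(rho, float), (self.n,)).copy()
        u = np.broadcast_to(np.asarray(u, float), (self.n,)).copy()
        p = np.broadcast_to(np.asarray(p, float), (self.n,)).copy()
        s = (np.zeros(self.n) if scalar is None
             else np.broadcast_to(np.asarray(scalar, float), (self.n,)).copy())
        E = p / (self.gamma - 1.0) + 0.5 * rho * u * u
        self._U = np.stack([rho, rho * u, E, rho * s])
        self.t = 0.0

    def primitives(self, U: np.ndarray | None = None):
        U = self._U if U is None else U
        rho = U[0]
        u = U[1] / rho
        p = (self.gamma - 1.0) * (U[2] - 0.5 * rho * u * u)
        s = U[3] / rho
        return rho, u, p, s

    @property
    def temperature(self) -> np.ndarray:
        rho, _, p, _ = self.primitives()
        return p / (rho * self.R)

    def total_mass(self) -> float:
        return float(np.sum(self._U[0] * self.volumes))

    def total_energy(self) -> float:
        return float(np.sum(self._U[2] * self.volumes))

    # -- numerics ---------------------------------------------------------

    def _ghosted(self, arr: np.ndarray, flip_sign: bool) -> np.ndarray:
        g = np.empty(arr.size + 4)
        g[2:-2] = arr
        # left ghosts mirror cells 0,1; right ghosts mirror cells -1,-2
        if self.bc[0] == "wall":
            g[0] = arr[1] * (-1.0 if flip_sign else 1.0)
            g[1] = arr[0] * (-1.0 if flip_sign else 1.0)
        else:
            g[0] = g[1] = arr[0]
        if self.bc[1] == "wall":
            g[-1] = arr[-2] * (-1.0 if flip_sign else 1.0)
            g[-2] = arr[-1] * (-1.0 if flip_sign else 1.0)
        else:
            g[-1] = g[-2] = arr[-1]
        return g

    def _rhs(self, U: np.ndarray, t: float):
        gamma = self.gamma
        rho, u, p, s = self.primitives(U)
        if (not np.all(np.isfinite(p))) or np.any(p <= 0) or np.any(rho <= 0):
            bad = np.flatnonzero(~np.isfinite(p) | (p <= 0) | (rho <= 0))[0]
            raise SolverError(
                f"non-physical state at t={t:.6e} s, cell {bad} "
                f"(x={self.x_centers[bad]:.4f}): rho={rho[bad]:.3e}, "
                f"p={p[bad]:.3e}", time=t, cell=int(bad))

        prims = []
        for arr, flip in ((rho, False), (u, True), (p, False), (s, False)):
            g = self._ghosted(arr, flip)
            slope = _minmod(g[1:-1] - g[:-2], g[2:] - g[1:-1])  # cells -1..n
            wl = g[1:-2] + 0.5 * slope[:-1]     # left state at faces 0..n
            wr = g[2:-1] - 0.5 * slope[1:]      # right state at faces 0..n
            prims.append((wl, wr))
        (rLf, rRf), (uLf, uRf), (pLf, pRf), (sLf, sRf) = prims
        rLf = np.maximum(rLf, _TINY)
        rRf = np.maximum(rRf, _TINY)
        pLf = np.maximum(pLf, _TINY)
        pRf = np.maximum(pRf, _TINY)

        F = _hllc(rLf, uLf, pLf, sLf, rRf, uRf, pRf, sRf, gamma)
        F = [np.asarray(f) for f in F]

        # hard-wall faces carry momentum only
        if self.bc[0] == "wall":
            for k in (0, 2, 3):
                F[k][0] = 0.0
        if self.bc[1] == "wall":
            for k in (0, 2, 3):
                F[k][-1] = 0.0

        corrections = None
        if self.diaphragm_face is not None:
            jd = self.diaphragm_face
            phi = 1.0 if self.open_fraction is None else float(
                np.clip(self.open_fraction(t), 0.0, 1.0))
            if phi < 1.0:
                a_l = np.sqrt(gamma * p[jd - 1] / rho[jd - 1])
                a_r = np.sqrt(gamma * p[jd] / rho[jd])
                pw_l = max(p[jd - 1] + rho[jd - 1] * a_l * u[jd - 1], _TINY)
                pw_r = max(p[jd] - rho[jd] * a_r * u[jd], _TINY)
                corrections = (jd, phi, pw_l, pw_r)
                for k in range(4):
                    F[k][jd] *= phi

        Af = self.area_faces
        dU = np.empty_like(U)
        for k in range(4):
            dU[k] = -(Af[1:] * F[k][1:] - Af[:-1] * F[k][:-1]) / self.volumes
        # p dA/dx momentum source (cell-centred pressure, well balanced)
        dU[1] += p * (Af[1:] - Af[:-1]) / self.volumes
        # spherical/duct metric: for A = r^2 this is the 2p/r source

        if corrections is not None:
            jd, phi, pw_l, pw_r = corrections
            dU[1][jd - 1] -= Af[jd] * (1.0 - phi) * pw_l / self.volumes[jd - 1]
            dU[1][jd] += Af[jd] * (1.0 - phi) * pw_r / self.volumes[jd]

        max_speed = np.max(np.abs(u) + np.sqrt(gamma * p / rho))
        return dU, max_speed

    def run(self, t_end: float, cfl: float = 0.45,
            callback: Callable[["EulerSolver"], None] | None = None,
            max_steps: int = 10_000_000) -> None:
        """Advance to t_end with SSP-RK2 at the given CFL number."""
        if self._U is None:
            raise SolverError("state not initialized")
        if not (0.0 < cfl <= 1.0):
            raise ValueError("require 0 < cfl <= 1")
        if callback is not None:
            callback(self)
        dx_min = float(np.min(self.dx))
        steps = 0
        while self.t < t_end:
            k1, smax = self._rhs(self._U, self.t)
            dt = min(cfl * dx_min / smax, t_end - self.t)
            U1 = self._U + dt * k1
            k2, _ = self._rhs(U1, self.t + dt)
            self._U = 0.5 * (self._U + U1 + dt * k2)
            self.t += dt
            steps += 1
            if callback is not None:
                callback(self)
            if steps >= max_steps:
                raise SolverError(f"step budget exceeded at t={self.t:.6e}",
                                  time=self.t)
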