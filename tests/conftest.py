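"""Shared fixtures: the expensive solver runs are session-scoped so the
chamber is simulated once and reused across the unit and acceptance
suites."""

import numpy as np
import pytest

from opcflow.opc_sim import (
    BurstModel,
    ChamberGeometry,
    lumped_blowdown,
    solve_quasi1d,
    solve_spherical_burst,
)


@pytest.fixture(scope="session")
def geometry():
    return ChamberGeometry()


@pytest.fixture(scope="session")
def burst():
    return BurstModel()


@pytest.fixture(scope="session")
def default_history(geometry, burst):
    """The default chamber run: 720 cells (2.5 mm), 60 ms."""
    return solve_quasi1d(geometry, burst, t_end=60e-3, n_cells=720, cfl=0.5)


@pytest.fixture(scope="session")
def coarse_history(geometry, burst):
    """Same configuration at doubled cell size (5 mm) for convergence
    checks."""
    return solve_quasi1d(geometry, burst, t_end=60e-3, n_cells=360, cfl=0.5)


@pytest.fixture(scope="session")
def lumped_default(geometry, burst):
    trace, qs = lumped_blowdown(geometry, burst, t_end=60e-3)
    return trace, qs


@pytest.fixture(scope="session")
def default_wavelet(burst):
    """Spherical precursor-burst trace at the specimen range."""
    return solve_spherical_burst(burst, r_target=0.127, t_end=2.0e-3)


@pytest.fixture(scope="session")
def sod_solution():
    """HLLC solution of the Sod tube at n=1000, t=0.2 plus the exact
    Riemann oracle."""
    from oracles import exact_riemann

    from opcflow._euler import EulerSolver

    n = 1000
    xf = np.linspace(0.0, 1.0, n + 1)
    solver = EulerSolver(x_faces=xf, area_faces=np.ones(n + 1), gamma=1.4,
                         R=1.0, bc=("transmissive", "transmissive"))
    xc = solver.x_centers
    left = xc < 0.5
    solver.set_state(np.where(left, 1.0, 0.125), 0.0,
                     np.where(left, 1.0, 0.1))
    solver.run(0.2, cfl=0.45)
    rho, u, p, _ = solver.primitives()
    exact = exact_riemann(1.0, 0.0, 1.0, 0.125, 0.0, 0.1, 1.4,
                          (xc - 0.5) / 0.2)
    return (rho, u, p), exact
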