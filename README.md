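# opcflow

Gas-dynamic characterization of the **jet-flow overpressure chamber
(OPC)**, a diaphragm-burst venting apparatus used as a laboratory model of
blast-mediated traumatic brain injury. The package answers, at desk scale,
the physics question behind the apparatus: *what loading does the specimen
actually experience, and how does it differ from free-field blast-wave
exposure?*

It is written for blast-physics and injury-biomechanics researchers who
need a transparent, scriptable model of the chamber rather than a full CFD
campaign: simulate the venting event, reduce Pitot-static records into
flow conditions, quantify free-flight loading on a specimen-scale sphere,
and compare everything against the canonical blast-wave relations.

## The physical model

The chamber is a closed vessel (0.6 m bore, 1.8 m long) split by a
partition into a short pressurized **Driver** and a long **Test Section**,
joined by a 14 cm aperture sealed with a Mylar diaphragm that bursts at a
nominal 138 kPa gauge. The package models the event with:

* **Quasi-1D Euler solver** (`opcflow.opc_sim.solve_quasi1d`): a
  finite-volume HLLC scheme on a duct of axially varying cross-section
  A(x), with the diaphragm as a partially open face whose open area ramps
  linearly over the ~0.3 ms petaling time. Downstream of the aperture the
  duct keeps the aperture cross-section for a short "jet column" spanning
  the specimen station before relaxing to the bore — the 1-D surrogate of
  the collimated jet. A passive scalar carried by the driver gas tracks
  the vented-gas front. Mass and energy in the sealed vessel are conserved
  to round-off.
* **Lumped blowdown oracle** (`lumped_blowdown`): two adiabatic volumes
  exchanging mass through a choked/unchoked isentropic orifice; its
  equilibrium pressure `(p_d V_d + p_t V_t)/(V_d + V_t)` cross-checks the
  field solver.
* **Spherical precursor burst** (`solve_spherical_burst`): the pressurized
  diaphragm bulge released in 1-D spherical symmetry, giving the weak
  precursor wavelet observed at the specimen.
* **Pitot-static reduction** (`opcflow.flow_reduction`): the Bernoulli
  partition q = p_stag − p_static, plus the isentropic inversion
  p_stag/p_static = (1 + (γ−1)/2·M²)^(γ/(γ−1)) with an automatic
  Rayleigh–Pitot branch when the implied M exceeds 1.
* **Blast-physics relations** (`opcflow.gas_core`): Friedlander waveform,
  shock Mach from overpressure, and the γ = 1.4 Rankine–Hugoniot partition
  of peak dynamic pressure,

      q = (5/2) Δp² / (7 p_amb + Δp),

  which quantifies the "blast wind" of a true free-field blast.
* **Free-flight loading** (`opcflow.free_flight`): a point-mass drag law
  m dv/dt = ½ ρ C_d A |u−v|(u−v) driven by the simulated jet history, and
  the inverse analysis of camera displacement tracks (Δv, impulse m Δv,
  mean acceleration).
* **Synthetic records** (`opcflow.synthetic_data`): seeded generators for
  the three-channel sensor suite and for camera tracks, used throughout
  the test suite for generator ↔ analyzer parameter recovery.

## Worked example

```python
from opcflow.gas_core import peak_dynamic_pressure
from opcflow.opc_sim import (ChamberGeometry, BurstModel, solve_quasi1d,
                             lumped_blowdown, jet_front_speed)
from opcflow.trace_dx import reverberation_period

# a 103 kPa free-field blast carries ~33 kPa of blast wind
print(peak_dynamic_pressure(103e3) / 1e3)    # 32.65 kPa

geom, burst = ChamberGeometry(), BurstModel()
h = solve_quasi1d(geom, burst, t_end=60e-3)  # ~20 s on one core

print(jet_front_speed(h))                    # 151.0 m/s
print(h.min_jet_temperature() - 273.15)      # -68.0 degC (cold jet)
print(reverberation_period(h.probe_traces["end_wall_static"],
                           window=(20e-3, 60e-3)) * 1e3)   # 7.92 ms

_, qs = lumped_blowdown(geom, burst, t_end=60e-3)
print(qs / 1e3)                              # 15.70 kPa quasi-static
print((h.mean_chamber_pressure((50e-3, 60e-3)) - 101325) / 1e3)  # 15.68
```

The numbers tell the story of the apparatus: the vented driver gas forms a
cold (−68 °C), fast (~150 m/s front) collimated jet whose damaging content
is almost entirely dynamic pressure, while the static pressure at the
specimen fluctuates below 20 kPa with partial-vacuum dips; both
compartments then equilibrate to a quasi-static level slightly above
ambient, approached in stages timed by the longitudinal reverberation of
the test section. This is the loading of a high-speed jet impingement, not
of a travelling blast wave.

A command-line surface wraps the same library:

```sh
opcflow simulate --out run/          # probe traces + manifest
opcflow reduce run/specimen_stagnation.csv run/specimen_static.csv
opcflow diagnose run/end_wall_static.csv
opcflow freeflight run/specimen_flow.csv
opcflow synth --seed 1
opcflow report --out run/            # full pipeline + benchmark table
```

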