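# Methods

This note records the physical models, numerical choices and measurement
conventions of `opcflow`, and what the desk-scale surrogate can and cannot
claim about the real apparatus.

## The chamber model

The apparatus is a sealed cylindrical vessel, 0.6 m bore and 1.8 m long,
partitioned into a pressurized Driver section and a Test Section connected
by a 14 cm aperture sealed with a frangible Mylar diaphragm (nominal burst
138 kPa gauge). The specimen sits on the jet axis ~12.7 cm downstream of
the aperture. Working gas is dry air treated as ideal and calorically
perfect: γ = 1.4, R = 287.05 J/(kg·K); laboratory ambient defaults to
101.325 kPa and 293.15 K (the study never states its ambient, so the
standard atmosphere is used). psi↔kPa conversion is fixed at
6.894757 kPa/psi. All pressures are SI absolute internally; gauge
conversion happens only at I/O boundaries (trace files are kPa gauge,
matching how chamber records are plotted).

### Geometry surrogate

The full event is axisymmetric; the package reduces it to quasi-1D Euler
flow in a duct of axially varying cross-section A(x):

* full bore in the driver, with a 4 cm cosine contraction to the aperture
  area at the partition;
* a **jet column** at the aperture cross-section extending 0.15 m past the
  partition. The specimen station (12.7 cm, i.e. 0.9 aperture diameters
  downstream) lies inside it, consistent with the potential core of a real
  starting jet which persists for several diameters;
* a 0.10 m cosine **relaxation cone** back to the bore, and full bore to
  the end wall.

The relaxation cone is a numerical device that reconciles the collimated
near field with the full test-section volume; states inside it are not
interpreted as jet physics (a quasi-1D diverging duct forces nozzle-like
supersonic over-expansion there, whereas the real jet boundary is a free
shear layer). This motivates the measurement convention for the minimum
jet temperature below.

The driver length is not published; the 0.20 m default is calibrated so
the two-volume equilibrium of a 138 kPa burst matches the observed
~15 kPa quasi-static level. With the surrogate duct volumes
(V_d = 0.0512 m³, V_t = 0.3989 m³) the equilibrium is 15.70 kPa gauge.

### Diaphragm

The diaphragm is a partially open face at the partition: the open-area
fraction φ(t) ramps linearly over the 0.3 ms petaling time (configurable,
`instantaneous` available). The Riemann flux through the face is scaled by
φ while the closed fraction contributes a wall pressure to each
neighbour's momentum; mass and energy are conserved for every φ. The
`shock_fraction` field records the observed ~10% incidence of a true
shock-front onset from non-ideal rupture; it parameterizes the synthetic
record generator, not the deterministic solver.

### Numerics

Finite-volume with minmod-limited linear reconstruction of primitives,
HLLC fluxes (PVRS wave-speed estimates), SSP-RK2 time stepping at
CFL 0.5, and the well-balanced p·dA/dx momentum source (a uniform
quiescent state is an exact steady state). Default resolution is 720
cells (2.5 mm); a 60 ms default run takes ~20 s on one core. End walls
are reflecting faces whose mass/energy/scalar fluxes are zeroed exactly,
so closed-domain mass and energy are conserved to machine precision
(~1e-15 relative over a full run; the suite asserts 1e-6). Validation:
the Sod shock tube at 1000 cells reproduces the exact Riemann solution to
L1 errors of 0.1–0.4% in (ρ, u, p); halving the chamber cell size moves
the quasi-static asymptote by <1% and the reverberation period by <3%.
The vented-gas front is the farthest cell downstream of the aperture
where a passive scalar advected with the driver gas exceeds 0.5.

The same kernel solves the spherically symmetric precursor burst
(A = r², exact shell volumes, reflecting origin, transmissive outer
boundary at 0.6 m, 1200 cells): a sphere of the bulge radius (0.07 m) at
the burst pressure released instantaneously. The release is instantaneous
because the bulge is the torn membrane's own gas pocket outboard of the
aperture plane; applying the petal ramp to the bulge surface instead
(`opening="ramp"`) halves the wavelet peak and is provided for
sensitivity analysis.

### Lumped blowdown

The 0-D cross-check treats the two compartments as adiabatic volumes
exchanging mass through an isentropic-nozzle orifice of the aperture area
(choked above the critical pressure ratio 1.893), receiving-side kinetic
energy dissipated. Total internal energy is then conserved, so both
volumes converge to (p_d·V_d + p_t·V_t)/(V_d + V_t). Integrated with an
adaptive RK45 at rtol 1e-8.

## Measurement conventions

* **Quasi-static level**: median of the final 10 ms of the
  specimen-station static trace. The lumped model predicts the
  *chamber-average* pressure; point probes superpose the standing
  reverberation wave (±3–4 kPa at 50–60 ms in 1-D, where only numerical
  dissipation damps it), so the 2% oracle-equivalence check compares the
  volume-averaged pressure (15.68 kPa) with the lumped equilibrium
  (15.70 kPa).
* **Reverberation period**: first prominent autocorrelation peak
  (prominence ≥ 0.05) of the end-wall static trace over 20–60 ms after
  subtracting a fitted offset exponential; parabolic lag refinement.
* **Minimum jet temperature**: minimum over the jet column (aperture
  plane to column end) within the first 10 ms. Including the relaxation
  cone would report its artificial over-expansion (−140 °C) rather than
  jet physics; the column minimum is −68 °C and the specimen-station
  minimum −65 °C.
* **Jet decay duration**: first time the specimen stagnation record
  enters and remains within 13.8 kPa (10% of burst gauge) of its
  quasi-static asymptote, applied to a 1 ms boxcar envelope of the trace
  so the metric measures the decay rather than the impulsive
  reverberation spikes the 1-D model overstates (the raw-trace figure is
  reverberation-dominated).
* **Rise time** is 10%→90% of the first major peak with interpolated
  crossings; a record is classified a shock front when it rises in under
  50 µs — far above the ~1 ns physical front (unresolvable at 800 kHz
  sampling) and far below the ~1.5 ms jet onset.
* **Pitot reduction** assumes the total temperature equals laboratory
  ambient (chamber temperature was not instrumented); total temperature
  is conserved across the probe bow shock, so the static-temperature
  recovery is exact in both branches. Samples where the stagnation
  channel reads below the static channel are clamped to q = 0 and
  flagged, never dropped.

## Free flight

The 40 mm sphere ballasted to 1.1 g/cm³ (mass 36.9 g) obeys the quadratic
drag law with C_d = 0.5 (subcritical sphere; the study matched Reynolds
number but stated no C_d, so the textbook flat-plateau value is used and
exposed in config). The local density comes from the simulation — the
cold jet is ~40% denser than ambient, materially increasing drag. Gravity,
lift, spin and holder contact are neglected over the 5 ms loading.
Track analysis uses central differences with second-order edges; for
camera-style tracks (≥12 frames) endpoint velocities come from a local
quadratic Savitzky–Golay derivative, exact for constant acceleration and
noise-averaging for pixel jitter. The mean acceleration is defined from
motion onset (first 0.1 mm of displacement) to the last sample; mean and
peak figures are reported side by side because the published 270 g mean is
not consistent with its own 15 m/s-in-5-ms velocity history (≈306 g), and
the package does not adjudicate.

## Synthetic records

The generator emulates the structure of the real sensor suite: a
~20 kPa / 0.2 ms precursor wavelet arriving ~0.4 ms after burst; a jet
decay from 138 kPa to the 15 kPa quasi-static level with a single
exponential (τ = 6 ms, so the envelope completes within ~18 ms) carrying
a 3% ripple at 1.3 kHz; staged convergence realized as an exponentially
damped smoothed-square train at the 8.5 ms reverberation period; a static
channel bounded below 20 kPa with a guaranteed partial-vacuum dip; a
monotone driver decay; Gaussian sensor noise (σ = 200 Pa) and optional
linear drift. The onset is a step with probability `shock_fraction`
(default 0.10) and otherwise a 1.5 ms ramp. Everything is deterministic
given the seed, and every parameter is recoverable by the diagnostics
within the tolerances asserted in the test suite — that round trip is the
backbone of CI. The generator does not emulate sensor transfer functions,
membrane-fragment strikes, or the 2-D directivity that makes the off-axis
probe see a weaker wavelet.

Blast-record generation pairs a Friedlander static channel with a dynamic
channel peaking at the Rankine–Hugoniot partition value, with a larger
decay exponent and a 1.5× longer positive phase, mirroring how blast wind
differs in shape from static overpressure.

## Known limitations

* **No ring vortex.** The starting-jet ring vortex is a 2-D structure;
  the quasi-1D surrogate cannot produce its >450 m/s local velocities or
  ~170 kPa dynamic-pressure transients. Consequently the simulated sphere
  reaches ~5 m/s in 5 ms rather than the observed ~15 m/s; the peak
  in-jet velocity and sphere acceleration are reported but not held to
  the published figures.
* **Blowdown rate vs. printed decay duration.** With the driver volume
  pinned by the 15 kPa equilibrium, an ideal 14 cm orifice empties it
  with a ~5 ms e-fold (field solver and lumped model agree), so the
  stagnation envelope settles in ~8 ms rather than the observed ~18 ms.
  Reconciling both printed figures would require an effective vent area
  of roughly 0.3–0.4 of the aperture (severe petal blockage), for which
  no principled value exists — and which would, in a 1-D model, also
  collapse the jet observables. The package keeps the ideal aperture and
  reports the discrepancy rather than hiding it behind a fitted
  discharge coefficient.
* **Ideal-burst wavelet.** The instantaneous 1-D bulge burst overshoots
  the axisymmetric non-ideal-rupture prediction of the precursor peak
  (~27 vs ~20 kPa at the specimen range); the ramped variant undershoots
  (~12 kPa). The truth sits between the two 1-D idealizations.
* **Under-damped reverberation.** In 1-D the longitudinal compression
  wave decays only by numerical dissipation, so late-time point-probe
  records oscillate more than real ones; conventions above are chosen so
  the reported observables are not contaminated by this.
* Passing the synthetic-data round-trip suite shows the analyzers recover
  what the generators encode; it does not validate sensor physics the
  generator omits (thermal transients, mounting vibration, fragment
  strikes).

## Problem sizes

Defaults were chosen so the whole characterization runs on one core in
about a minute: 720 cells × 60 ms for the chamber (≈37k time steps),
1200 cells × 2 ms for the spherical burst, RK45 at rtol 1e-8 for the
blowdown ODE and the sphere coupling, 800 kHz trace resampling
everywhere.
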