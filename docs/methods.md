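# Methods

## The model

`beadchain` simulates a macroscale physical analog of a diffusive polymer: a
chain of 14 spherical resin beads (radius `rb` = 3 mm) alternating with 15
small crimp tracers (modelled as spheres of radius `rt` = 0.75 mm), strung
between two fixed anchors 101 mm apart, and buffeted by random forces that
stand in for the grains of an air-fluidized bed.  The equations of motion
for each mobile particle are Newtonian,

    m dv/dt = F_linear + F_angular + F_string + F_damp + F_kick,

with four deterministic force laws and one stochastic one:

- **Linear (stretch) bonds** between adjacent particles, harmonic about the
  contact distance `rb + rt`: `F = -kl (R - (rb + rt)) r̂`, `kl` = 1 N/m.
- **Angular (bend) bonds** on each triple of adjacent particles, harmonic in
  the bend angle about the straight configuration: the end-particle force
  magnitude is `ka |θ - π|` with `ka` = 1e-2 N/rad.  Internally this is
  realized as the exact gradient of `U = ½ ka ℓ̄ (θ - π)²` (`ℓ̄` = mean arm
  rest length), so the triple conserves momentum and the forces are exactly
  `-∇U`.  The study's parameter table is ambiguous about the units of
  `ka` (N/m in the table, N/rad as used in the force expression); we adopt
  N/rad, under which the bending force scale matches the kick scale
  (~1e-2 N) and the chain bends visibly with a persistence of order ten
  links, as observed for the physical chains.  The alternative reading
  (`ka` as an energy constant with an extra 1/arm factor) would stiffen
  bending by the factor 1/arm ≈ 270, making the chain an essentially rigid
  rod.
- **String bonds** from each end crimp to its anchor: no force while the
  anchor distance is below the string rest length `ℓ0` = 12 mm, linear
  restoring `ks (ℓ - ℓ0)`, `ks` = 5 N/m, beyond.
- **Viscous damping** `-kv v` on every mobile particle (see the damping
  section below).
- **Kicks**: once per timestep, each targeted particle receives a force
  `kr·(Px, Py, Pz)` held constant over the step, `kr` = 1e-2 N, with the
  `Pi` drawn independently per component and per step from either a standard
  normal or a standard Laplace.  The Laplace draw follows the two-uniform
  construction `P = -log U1` if `U2 ≤ 0.5` else `+log U1`.  By default all
  mobile particles are kicked (crimps are immersed in the grains just as
  beads are); a `beads_only` switch restricts the forcing to the resin
  beads.

No excluded-volume, gravity or hydrodynamic terms are included: the
physical chain is density-balanced to neutral buoyancy, and the bed enters
only through the kicks and the damping.  These are deliberate omissions and
the main reason the simulation is an *analog* rather than a model of the
bed's multiphase flow.

Masses follow the study's tabulated particle density of 5e-3 kg/m³ times each
sphere's volume.  That density is physically implausible (beads of
~6e-10 kg), but it is the stated parameterization and - importantly - it
puts the dynamics deep into the overdamped regime `m/kv ≪ dt` on which the
study's central mechanism relies; a "corrected" plausible density would
make the velocity an integral over thousands of kicks and therefore
Gaussian by the central limit theorem regardless of kick shape.  The mass
assignment can be overridden per particle kind (`mass_per_particle`).

## Damping: the one re-derived parameter

The study calibrated `kv` so that simulated mean bead speeds matched the
tracked experimental tracers, a ~0.1 m/s scale (the package reproduces this
procedure in `damping_calibration_sweep`).  The study's table nonetheless
prints `kv` = 1e-4 N·s/m, which implies a terminal speed `kr/kv` = 100 m/s
and per-step displacements of ~1 cm - three bead diameters per timestep.
In that regime the chain's geometric nonlinearity dominates and the
velocity distribution decouples from the forcing shape entirely: both
Laplace and Gaussian kicks yield heavy-tailed velocities with fitted
exponent β ≈ 1 (the suite's `test_printed_damping_regime_loses_forcing_shape`
demonstrates this), so the study's Gaussian-forcing result (β = 2) cannot
be obtained under the printed value.  The printed value also contradicts
the stated calibration by three orders of magnitude.

The package therefore distinguishes:

- `ForceField()` defaults: the printed table, including `kv` = 1e-4;
- the *calibrated* configuration (`study_forcefield("calibrated")`,
  `CALIBRATED_DAMPING`): `kv = kr / v_target` = 0.1 N·s/m for a target mean
  per-component speed of 0.1 m/s, the experiment-scale value implied by the
  stated calibration.

The headline forcing-shape experiment uses the calibrated configuration.
The choice of 0.1 m/s as the target is not delicate: the shape-propagation
result requires only that (i) velocities relax within a timestep
(`m/kv ≪ dt`, satisfied by orders of magnitude) and (ii) per-step
displacements stay small against the bead size (`(kr/kv)·dt ≪ rb`, i.e.
`kv ≫ 3e-4`), so any damping in the broad plateau above ~1e-2 N·s/m gives
the same exponents.

## Integration

With the default masses the velocity relaxation time `m/kv` is 1e-7 s or
less against a 1e-4 s timestep - explicit treatment of the damping force is
violently unstable (`kv·dt/m ≫ 1`).  The default `split_damping` integrator
is therefore a kick-drift-kick scheme whose velocity half-updates solve
`m dv/dt = F - kv v` exactly with the force frozen:

    v ← v e^(-γ h/2) + (F/kv)(1 - e^(-γ h/2)),   γ = kv/m.

The scheme is stable for arbitrarily strong damping, reproduces the
terminal velocity `F/kv` as an exact fixed point, and reduces to plain
velocity-Verlet (symplectic, energy-conserving) as `kv → 0`.  A textbook
`verlet` mode with damping as an explicit force is kept for reference and
for the undamped limit.

Stiff bonds are resolved by splitting each timestep into equal substeps
with the kick frozen (zeroth-order hold, consistent with per-step kick
updates).  The substep count is chosen automatically: for each particle
with total incident stiffness `k`, the substep `h` must satisfy the
overdamped position-update bound `k·h/kv ≤ 0.5` where the velocity fully
relaxes within a substep, or the oscillatory bound `√(k/m)·h ≤ 0.5`
otherwise.  Under the calibrated configuration one substep suffices; the
printed-damping configuration needs 32.  Non-finite state aborts the run
with diagnostics (step index, largest force and speed), backstopping the
heuristic.

Randomness is one seeded stream per run in (step, particle, component)
order with the two uniforms of a Laplace draw innermost, so trajectories
are reproducible bit-for-bit given the seed.  The compiled kernel is a
transcription of the pure-numpy force reference and is asserted equal to it
(to 1e-12) on random configurations in the test-suite; the bonded forces
themselves are verified as exact negative gradients of the declared
potentials by central differences.

## Analysis

Velocity distributions are summarized by the exponential-power
(generalized normal / stretched-exponential) family
`P(v) ∝ exp(-α|v-μ|^β)`: β = 2 is Gaussian, β = 1 Laplace.  β is fitted by
profile maximum likelihood on the median-centred sample - for fixed β the
scale MLE is closed-form, leaving a one-dimensional optimization - with a
seeded percentile bootstrap for the confidence interval.  A count-weighted
least-squares fit to the log-histogram (Freedman-Diaconis bins, empty bins
dropped) is available for visual parity with semi-log density plots, but
histogram fits are bin-sensitive and never the default.  Per-sign
exponential rates (`λ = 1/mean`, fitted separately on positive and negative
velocities, zeros excluded) mirror the way experimental semi-log plots are
usually annotated.

The headline experiment pools the recorded instantaneous velocities of the
five centre-most crimps (crimps 6-10 of 15; the ends are constrained by the
strings) over the two in-plane components x and y, mimicking the 2D X-ray
projection in which the out-of-plane component is unobservable.  Recording
follows the study protocol: 4e5 steps with the first 1e5 discarded as
equilibration and every 100th step kept, giving 3000 frames and 30,000
pooled samples.

For tracked (or synthetic) position tables, velocities are finite
differences at the frame interval.  The default scheme is central
differences on interior frames with one-sided differences at track ends; a
missing frame contributes no spanning estimate.  Central differencing
low-pass filters the velocity process: when per-frame velocities are
*uncorrelated* it averages two independent displacements and biases a
fitted non-Gaussian exponent toward 2 (a Laplace sample fits at β ≈ 1.3).
The `scheme="forward"` option uses each adjacent frame pair once and is the
exact inverse of the synthetic generator's displacement construction; the
end-to-end recovery tests use it for that reason.  For real beads, whose
velocities correlate over neighbouring frames, the two schemes agree
closely and the less noise-amplifying central scheme is the default.

## Synthetic tracks

The generator emulates the tracked output of the experiment: a handful of
tracers, 2D positions at 30 frames/s in millimetre units, with per-frame
displacement equal to an independent per-component velocity draw (Laplace
or Gaussian, configurable scale) divided by the frame rate, optional
Gaussian detection noise on each position, and i.i.d. frame dropout
emulating motion-blur detection failures.  What it deliberately does *not*
emulate: frame-to-frame velocity correlation, the spatial inhomogeneity of
a bubbling bed, tracking-identity errors, or the kinematic coupling between
tracers on one chain.  Passing the synthetic end-to-end tests therefore
demonstrates that the I/O + differencing + fitting pipeline is correct and
unbiased, not that the experimental distributions themselves are
recoverable from real video.

## Bed design formulas

The minimum fluidization velocity solves the Ergun pressure-drop/weight
balance; with void fraction ε = 1 - 0.58, 1 mm grains of material density
570/0.58 ≈ 983 kg/m³, sphericity 1 and 20 °C air (ρ = 1.2 kg/m³,
μ = 1.8e-5 Pa·s - standard assumptions, all overridable), the positive
root is U_f = 0.319 m/s, and the operating point 0.55 m/s exceeds it by
1.7×.  The quadratic is solved in the cancellation-free form
`2c/(b + √(b² + 4ac))` because the viscous coefficient can dominate the
discriminant.  U_f *increases* with void fraction over the physical range
(both Ergun coefficients carry ε³ in the denominator).

## Hollow-bead density balancing

The effective density of a printed bead is the material volume (spherical
shell + protrusion cylinder - threading bore, the bore crossing two wall
thicknesses and the protrusion) times the resin density, over the outer
sphere's envelope volume.  For the study geometry (0.4 mm walls) this gives
0.44 g/cm³, consistent with the ~0.4 g/cm³ found to keep the chain
neutrally buoyant.  The inverse problem - wall thickness for a target
density - is solved by bracketed root-finding to 1e-9 relative; the
thickness-density relation is strictly increasing over the printable range
(it can reverse only when the walls grow thick enough that the bore removes
more material than the shell gains, far outside that range).

Two lengths are reported and deliberately not reconciled, as they disagree
in the source description: the fabrication contact length (beads +
protrusions + crimps + slack = 126 mm ≈ the quoted "approximately
12.5 cm") and the simulated sphere-contact span (106.5 mm from the model
radii).

## Problem sizes and defaults used in validation

The acceptance computations use the full study protocol (4e5 steps, 29
mobile particles; a run takes seconds with the compiled kernel).  Unit
tests use 1-3-bead chains and 1e3-1e4-step runs; the stochastic recovery
checks use 1e4-sample fits, 50-replicate repetition rates, and 1e6-draw
moment checks, each sized so the assertion tolerance sits several standard
errors from the truth under the fixed seeds.

## Known limitations

- The printed-damping configuration is simulated faithfully but cannot
  reproduce the study's Gaussian-forcing exponent (see the damping
  section); conclusions about the physical bed rest on the calibrated
  configuration.
- The bend potential interpretation (N/rad) is a documented choice between
  two readings the source leaves ambiguous.
- No contact/excluded-volume forces: the chain can self-cross, which the
  physical chain cannot.  At the calibrated operating point configurations
  stay near-taut and self-crossing is rare, but the simulator does not
  detect it.
- Persistence-length estimation (the source's alternative damping
  calibration notion) is not implemented; the procedure is unspecified and
  the mean-speed sweep is provided instead.
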