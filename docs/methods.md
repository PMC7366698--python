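# Methods

This note records the models implemented in `slantdep`, their assumptions,
the numerical choices behind them, and what the synthetic data does and does
not emulate.

## Dielectric model

The Clausius–Mossotti factor is evaluated with the −iσ/ω sign convention,
ε\* = ε₀ε_r − iσ/ω. Frequencies are always ordinary frequencies f (Hz),
converted internally to ω = 2πf; the package never accepts rad/s directly,
which avoids the classic factor-of-2π ambiguity. The particle enters through
its effective conductivity σ_e = 2K_s/R + σ_b — for micron polystyrene the
surface term dominates (σ_e ≈ 8×10⁻⁴ S/m at R = 2.5 µm against a bulk term
of 10⁻¹⁵ S/m).

Default material parameters: medium ε_r = 76.4 (DI water; the 20% glycerol
used for density matching is assumed not to change the permittivity),
σ_m = 2.03×10⁻³ S/m (measured solution conductivity), µ = 1.0×10⁻³ Pa·s
(water at room temperature; the medium viscosity is not part of the
electrical data set, so the water value is the default and is overridable).
Particle ε_r = 2.4, K_s = 10⁻⁹ S, σ_b = 10⁻¹⁵ S/m (polystyrene literature
values).

Exact evaluation of these formulas at 6 MHz gives Re(CM) between −0.4749
(5 µm beads) and −0.4765 (20 µm), converging to the high-frequency limit
(2.4 − 76.4)/(2.4 + 152.8) = −0.4768; the spread across sizes is under 0.4%,
which is why a single operating frequency can treat all bead sizes as
electrically equivalent. CM spectra default to log-spaced grids with 60
points per decade.

Scope limits: single-shell homogeneous spheres only. No multi-shell (cell)
models, electrorotation, AC electro-osmosis or electrothermal flow.

## Field solver

Model: the 2D cross-section [0, W_dom] × [0, h] with two zero-thickness
electrode strips on the floor (the real metal layer is ~10⁻⁷ m, three orders
below the channel height). For a homogeneous fluid the electro-quasi-static
operator ∇·[(σ + jωε₀ε_r)∇V] = 0 has a constant complex coefficient, which
cancels: the solver is a real Laplace solver, and frequency affects the
physics only through the CM factor. Boundary conditions are Dirichlet
±Vpp/2 on the electrode strips and homogeneous Neumann (insulating
glass/PDMS) on every other boundary segment.

Numerical choices:

- **Domain truncation.** The lateral padding beyond each outer electrode
  edge defaults to max(2h, w). Doubling it moves the top-line figure of
  merit by ~0.001% (checked in the test suite against a 1% bound).
- **Mesh.** Rectilinear tensor grid graded geometrically (growth 1.1)
  toward the four electrode edges and toward the electrode plane, with
  initial spacing min(g, w, h)/12 and cap h/8; each refinement level halves
  both. The gap is always resolved by ≥ 12 intervals. The potential has
  r^1/2 corner singularities at the electrode edges, which the grading
  resolves where it matters; the top line y = h is the smoothest part of
  the solution and converges fastest.
- **Discretization.** Nonuniform 3-point second differences per direction
  (5-point Laplacian), reflecting ghost nodes for Neumann boundaries. The
  scheme is an M-matrix, so the discrete maximum principle holds exactly.
- **Linear solve.** Dirichlet unknowns are eliminated before factorization
  so the free-node system stays uniformly scaled (all rows ~1/h²); mixing
  O(1) identity rows with O(10¹²) Laplacian rows was observed to cost ~3
  digits of accuracy in the direct solve. The reduced system is solved by
  sparse LU and verified against a 10⁻¹⁰ relative residual.
- **Derived fields.** E = −∇V and ∂(E²)/∂x use centred second-order
  differences on the nonuniform grid (one-sided at boundaries). On the top
  line E_y vanishes identically (Neumann wall), so the figure of merit
  reduces to ∂(E_x²)/∂x there.
- **Figure of merit.** max |∂(E²)/∂x| over the top line, excluding the two
  lateral domain-edge nodes so truncation artifacts cannot supply the
  maximum. An optional lower evaluation height is not provided: particles
  in deep channels may not reach the very top, but no alternative height is
  better justified, and the quantity is used comparatively across
  geometries.
- **Verification.** Pointwise agreement with a closed-form conformal-map
  oracle (two semi-infinite coplanar plates with a finite gap in the upper
  half-plane, plus the exact zero-gap wall correction obtained by mapping
  the Neumann-reflected strip with ζ = exp(πz/2h)) is 0.6% at refinement
  level 2 in the region r < h/2 around the gap, excluding a ring of radius
  g/4 around the two corner singularities where pointwise finite-difference
  values converge only as √h. Manufactured-solution tests confirm
  second-order field differentiation; self-convergence of the figure of
  merit is below 2% per refinement at the study geometries.

The solver is strictly 2D: no variation along the channel length, no double
layer at the electrodes, no Joule heating.

## Geometry sweep

Default grids mirror the study: h ∈ {25, 40, 60, 75} µm,
w ∈ {10, 20, …, 110} µm, g ∈ {5, 10, 15, 20, 30, 40, 50} µm, all at the 2 Vpp
reference drive. The reference gap for width sweeps is 10 µm (the
fabrication choice). The **critical width** per height is operationalized as
the smallest width whose FOM is within 5% (configurable) of the width-sweep
maximum; a result equal to the largest swept width is flagged
right-censored. Enhancement percentages are plain relative differences,
100·(FOM_b − FOM_a)/FOM_a. Sweeps are deterministic and cacheable by
parameter hash; a failed cell is recorded and skipped, not fatal.

Monotonicity caveat: adjacent sweep cells can differ by less than the
discretization error (~0.5% at the default mesh), so trend assertions in the
tests allow a 1% tolerance rather than demanding strict ordering of floats.

## Transport model

The deflection criterion v_crit = F_DEP/(6πµR sin θ) is this package's
operationalization of "DEP dominant over drag"; it balances the barrier
force normal to the electrode against the normal drag component, treating
the particle slip velocity as the mean channel velocity V̇/(W·h) times a
profile factor (default 1.0; a parabolic-profile evaluation at the particle
height is a straightforward extension). Consequences used as test oracles:
v_crit ∝ R² (R³ force over R drag), max V̇ ∝ Vpp², and max V̇ = v_crit·W·h so
equal fields favour taller channels while the actual FOM(h) dependence
overwhelms that area effect.

The angle trade-off couples the 1/sin θ single-barrier advantage of shallow
angles with a retry model over the n electrode pairs that fit in the
channel: crossing survival decays as exp(−κ(v/v_crit − 1)) above v_crit,
overall deflection is 1 − (1 − p_single)^n, and the reported capacity is the
largest flow rate with deflection probability ≥ 0.99. A single pair is a
hard threshold. κ defaults to 0.2, a value for which the study's pair-count
layout (1 pair at 5°, 24 at 45°, intermediate counts interpolated ∝ tan θ as
configuration defaults) produces an optimum at an interior angle; this is a
model hypothesis exercised only through ranking properties, never through
quantitative targets. Gravity and buoyancy are omitted (density-matched
suspensions); inertial lift, particle–particle and wall interactions and
Brownian motion are out of scope, and no absolute µL/min calibration is
attempted.

## Synthetic experiments

The generator emulates the *structure* of the throughput measurements: a
condition grid (bead sizes 5–20 µm or 5–10 µm, voltages 2–10 Vpp, heights
25–75 µm, angles 5°–45°), three replicates per condition, and measurements
throughput = slope·Vpp²·(1 + ε) with ε ~ N(0, 0.05) truncated at zero. The
5% multiplicative noise is a choice of plausible bench-scale repeatability
(no numeric error bars are published to fit); the voltage range 2–10 Vpp is
sampled at five evenly spaced levels. All randomness flows through one
explicit seed. What this does **not** emulate: outlet particle counting,
image analysis, device-to-device calibration, or the published absolute
throughput values — so passing tests show the analysis pipeline recovers
what the model put in, not that the model matches any specific device.

The fit regresses throughput on Vpp² by ordinary least squares and attaches
a resampling-based confidence interval: the slope SE comes from
bootstrapping replicates within each voltage level (500 draws, inflated by
√(n_rep/(n_rep−1))), with a t reference at n_rep − 1 degrees of freedom —
the SE rests on n_rep independent replicates, so wider small-sample
quantiles are appropriate; with the regression df the interval undercovers
(84.8% measured against the 95% nominal at three replicates). Measured
coverage of the shipped interval is ~97% at the default study conditions.
The intercept is fitted but expected ≈ 0; slope recovery, not slope values,
is the tested claim.

## Problem sizes

Default meshes run 1–6×10³ nodes per solve (~0.1 s); the acceptance script
solves its eight study geometries at refinement level 2 (2.5–3.7×10⁴ nodes,
~0.3 s each), where the figure of merit is converged to well under 2%. The
Monte-Carlo calibration of the slope-recovery interval uses 500 seeded
synthetic experiments.

## Known limitations

- The 2D cross-section ignores the field's variation along the electrode
  line near pad terminations.
- The force balance is quasi-static and single-particle; it cannot predict
  partial collection efficiencies between 0 and 1 for a single pair.
- The retry-model decay κ is not identifiable from any published quantity;
  rankings that depend on κ are reported as model behaviour, not
  predictions.
- Enhancement percentages carry the residual discretization error of both
  solves they compare (≲2% each at the default acceptance mesh).
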