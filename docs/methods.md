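# Methods

## Model

`porewalk` simulates a rigid spherocylinder (capsule: a cylinder of length
*l* and diameter *d* capped by two hemispheres, aspect ratio *f* = 1 + *l/d*)
diffusing through a cylindrical channel. The channel diameter is the unit of
length; the channel axis is *z*, the entrance plane is *z* = 0 and the exit
plane *z* = *L* (default *L* = 14.3). The dynamics is the overdamped
(Wiener-process) limit: no velocities, no hydrodynamics — positions and
orientations evolve by independent Gaussian increments subject to hard-wall
rejection.

Each time step consists of, in order:

1. **Translation attempt.** A displacement with independent N(0, σ<sub>x</sub>)
   components (isotropic; σ<sub>x</sub> = 0.05 by default). The move is
   rejected — the particle stays put — if the displaced capsule would
   intersect the cylindrical wall or the center's *z* would become negative
   (reflecting entrance).
2. **Rotation attempt.** A rotation axis Â uniform on the sphere, through
   the particle center, and an angle Δφ ~ N(0, σ<sub>φ</sub>(Â)) with the
   equipartition scaling
   σ<sub>φ</sub>(Â) = σ<sub>x</sub> (Âᵀ M Â)<sup>−1/2</sup>,
   where M is the capsule's inertia tensor. The rotation is rejected if the
   reoriented capsule would intersect the wall. The axis vector is
   renormalized after every accepted rotation (drift < 1e-12 per step is
   removed immediately).
3. The step counter advances by exactly 1 whether or not either attempt was
   accepted — rejected attempts cost time.

A trajectory starts at the origin aligned with the channel axis and ends
when the center reaches *z* ≥ *L* (absorbing exit); the step count at that
moment is the first-passage time (FPT) and the exit angle θ = ∠(û, ẑ) is
recorded at absorption, after the accepted translation and before any
further rotation. Trajectories that hit the safety cap
`max_steps` (default 100·L²/σ<sub>x</sub>², floored at 10⁴) are flagged
censored, never dropped.

### Inertia tensor and mass convention

In the body frame (z along the particle axis), with *r* = *d*/2,

* M<sub>xx</sub> = M<sub>yy</sub> = m₁(l²/12 + r²/4) + 2m₂(2r²/5 + l²/4 + 3lr/8)
* M<sub>zz</sub> = (m₁/2 + 4m₂/5) r²

with m₁ the core mass and m₂ one cap's mass, m₁/m₂ = 3l/(2r) (uniform
density). Only the mass *ratio* is physically fixed; we normalize
m₁ + 2m₂ = 1 so that σ<sub>φ</sub> depends on shape alone. This is a genuine
convention choice: it sets the absolute rotational step scale and therefore
the absolute values of rotation-limited observables. The transverse formula
is exactly the uniform-density capsule result (the cap term
2r²/5 + l²/4 + 3lr/8 follows from the parallel-axis theorem through the cap
centroid at l/2 + 3r/8); the test suite verifies it against an independent
cross-section quadrature to 1e-6 relative.

Because M<sub>xx</sub> = M<sub>yy</sub>, the lab-frame contraction
Âᵀ M Â needs no roll convention: it equals
M<sub>zz</sub> c² + M<sub>xx</sub>(1 − c²) with c = Â·û.

### Collision test

The capsule's radial reach from the channel axis is a convex function of
position along its core segment, so "capsule inside cylinder" reduces
exactly to checking the two core-segment endpoints:
max(‖e₊‖, ‖e₋‖) + r ≤ 0.5 with e± the lateral coordinates of
x ± (l/2)û. The channel ends are not material walls: only the center's *z*
is constrained (caps may protrude axially past the entrance and exit). The
reduction is cross-checked against a 10⁵-point surface-sampling oracle;
configurations within 5·10⁻³ of exact tangency are excluded from that
comparison because pointwise sampling cannot decide them.

### Interpretation choices

The update rule "retry until no collision" with rejected attempts counted in
the elapsed time is implemented as single-attempt rejection (stay in place,
advance time) — the two formulations generate identical processes when every
attempt costs a step. Absorption uses *z* ≥ *L*, tested after the
translation sub-step only (rotations cannot move the center).

## Randomness and reproducibility

An ensemble takes one master seed; per-trajectory sub-seeds are spawned with
`numpy.random.SeedSequence.generate_state`. The compiled kernel reseeds its
internal MT19937 generator per trajectory and draws, per step, in a fixed
order: three translation normals, two uniforms for the rotation axis
(cos-polar + azimuth), one rotation-angle normal. Every trajectory is
therefore bit-reproducible from its sub-seed, serial and parallel
aggregation give identical results, and any run directory can be regenerated
from `run_meta.json` alone. A pure-Python `step` mirrors the kernel's
accept/reject logic for readable testing; it draws the rotation axis by a
different (equally uniform) recipe, so it matches the kernel in distribution
and in logic, not draw-for-draw.

## Observables

* **MSD / diffusion type.** msd(t) = ⟨|x(t) − x(0)|²⟩ over trajectories
  still inside the channel, on the recording grid (default stride 100
  steps), fitted as 2D·t^α by unweighted ordinary least squares in log-log
  over [0.01·t<sub>min</sub>, t<sub>min</sub>], where t<sub>min</sub> is the
  minimal observed FPT. Restricting to t ≤ t<sub>min</sub> keeps every
  trajectory in the average and keeps the absorbing end out of the window;
  starting at 0.01·t<sub>min</sub> skips the early transient at the
  reflecting entrance. Fits need ≥ 5 grid points.
* **Survival.** S(t) is the Kaplan–Meier estimate (lifelines) over the FPT
  samples, censored trajectories entering at `max_steps`; with no censoring
  it is 1 − ECDF. The tail S(t) ∝ A·e^(−λt) is fitted by least squares on
  log S for t above the median FPT, excluding the last 1% of grid points
  where the estimator jumps between its last few values. Fits need ≥ 10
  tail points.
* **Exit orientation.** θ is histogrammed on [0, π] (36 bins by default)
  and divided by the exact per-bin integral of sin θ (the sphere measure),
  then renormalized to unit integral — an isotropically oriented particle
  gives a flat density 1/π. Using the exact bin integral instead of
  sin(center) keeps the end bins finite. θ is not folded at π/2 despite
  head–tail symmetry, matching the [0, π] integration convention. The
  spread is the second moment σ = (∫θ²p(θ)dθ)^{1/2} by midpoint quadrature;
  a flat density gives π/√3 ≈ 1.8138 (printed as 1.814). The raw
  (unreweighted) density is emitted alongside for comparison.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| σ<sub>x</sub> | 0.05 | translational step SD per component (channel widths) |
| L | 14.3 | channel length |
| channel radius | 0.5 | fixed — the diameter is the unit length |
| n_traj | 5000 | ensemble size |
| d | 0.03–0.9 | particle diameters studied |
| f | 1–5.6 | aspect ratios studied |
| record_stride | 100 | position-recording interval (steps) |
| max_steps | 100·L²/σ<sub>x</sub>² | censoring cap (≈ 8.2·10⁶ at defaults) |

## What the simulations do and do not show

The generator *is* the model: there is no external data. Passing tests show
that the implementation reproduces the closed-form limits of this idealized
model (1D reflecting–absorbing Wiener FPT statistics for a thin sphere,
free-walk MSD, flat exit-angle density for isotropic orientations) and its
qualitative shape dependence. They do not validate the model against real
nanopore transport: hydrodynamic wall coupling, anisotropic translational
mobility, external driving and particle–particle interactions are all
outside the model.

Two quantitative caveats discovered while validating:

* The thin-particle ("point-particle") limit is not as clean as the 1D
  closed forms suggest: lateral wall rejections occur at a rate set by
  σ<sub>x</sub>/(channel radius) = 0.1 *independently of d* (the lateral
  position equilibrates to uniform over the accessible disk, and ~8% of
  proposals step outside it). The mean FPT of the d = 0.03 sphere therefore
  sits ~9% above L²/σ<sub>x</sub>², at the edge of the 10% oracle band used
  in the tests.
* For thick particles the same mechanism is strong (translation acceptance
  ≈ 0.33 at d = 0.9), which lowers the effective axial diffusion constant,
  the fitted D, and λ, and raises the median FPT, all by the same factor.
  Thickness dependence of the median and thickness independence of λ are
  therefore mutually exclusive in this model; the test suite checks both
  orderings and reports which ones this implementation actually satisfies.

## Problem sizes

Ensemble statistics in the tests and in `scripts/acceptance.py` use 500
trajectories per (f, d) grid cell (the corner grid d ∈ {0.03, 0.45, 0.9} ×
f ∈ {1, 2.9, 5.6}) and 5000 trajectories for the thin-sphere oracle checks
— the corner grid is the package's reduced rendering of the full 8×8-style
sweeps a production study would run with `porewalk sweep`.
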