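# Methods

`brushwear` is a three-dimensional discrete-element (DEM) simulator of
manual toothbrushing: 42 flexible bristle tufts, each a worm-like-chain
(WLC) of bonded particles, are scrubbed over a simplified enamel tooth
model while every tip–tooth sliding contact deposits Archard wear volume on
a surface map.  This note records the model, its parameters, the numerical
choices, and what the implementation can and cannot say about real
brushing.

## Bodies and materials

Two isotropic materials parameterise everything (SI units):

| property | acrylic (brush) | enamel (tooth) |
|---|---|---|
| Young's modulus E | 3.4 GPa | 60 GPa |
| Poisson ratio ν | 0.3 | 0.3 |
| density ρ | 1185 kg/m³ | 3000 kg/m³ |
| hardness H | 0.22 GPa | 0.92 GPa |
| friction μ (all pairs) | 0.18 | 0.18 |

The coefficient of restitution e that controls contact damping is not a
tabulated property of either material; it is a configuration parameter
with default **e = 0.3** (strongly dissipative, appropriate for damped
plastic-on-mineral impacts).  Sensitivity: e enters only the velocity-
proportional damping term; the quasi-static sliding forces that dominate
the wear output are unchanged by e, while impact transients (groove-wall
hits) are stronger at larger e.

## Bristle tufts: WLC connected particles

A real tuft bundles ~40 filaments; here each tuft is one aggregate beam of
diameter d = 1.8 mm and length 10.8 mm, discretised as **8 particles** of
the same diameter spaced l₀ = 10.8/7 mm, the **top two clamped** into the
head (kinematic: their positions are slaved to the head frame and their
equations of motion are never integrated; they act as infinite-mass bodies
in contacts).  Per-particle mass is the solid-cylinder segment ρAl₀.

Bonded interactions carry three energies (forces are their exact analytic
gradients, verified against central differences to 1e-6 relative):

- stretching `H_S = ½ k_s Σ (l_i − l₀)²` with `k_s = EA/l₀`;
- bending `H_B = k_bend Σ_joints (1 − t̂_i·t̂_{i+1})` with
  `k_bend = EI/l₀`, `I = πd⁴/64`;
- torsion `H_T = ½ k_T Σ (γ_i − γ₀)²` with `k_T = GJ/l₀`, `J = πd⁴/32`;
  γ is a scalar twist per bond integrated from the relative spin of its two
  particles (no full per-particle orientation state).

Torsion is implemented but **off by default** in brushing runs: bending is
by far the dominant deformation mode of a scrubbed bristle and the engine
generates no torque sources when tips do not roll (rolling is not
modelled; tangential forces use translational slip only).

### Cantilever length convention

A chain of particles spaced l₀ with joint springs EI/l₀ is the staggered
discretisation of a continuum beam in which particle k sits at arclength
(k − ½)l₀ and the clamp plane lies half a segment above the first free
joint.  The 8-particle, 2-clamped tuft therefore corresponds to a
continuum cantilever of effective length **6.5 l₀ = 10.03 mm** (6 active
joints), and this length is used for both the Euler–Bernoulli and elastica
references in the validation bench.  With the naive anchor-to-tip length
(6 l₀) the discrete tip compliance overshoots FL³/3EI by 26% for any
discretisation of this type — a property of the convention, not of the
model — whereas the half-segment convention agrees to ~0.6% at small loads.
The bench states the convention because the reported percent error depends
on it.

### Validation bench

`validation.elastica_deflection` solves the inextensible large-deflection
cantilever EI θ″(s) = −F cos θ, θ(0) = 0, θ′(L) = 0 by shooting (brentq on
the root curvature, `solve_ivp` at rtol 1e-10); the DEM side applies a dead
transverse tip load and relaxes to equilibrium.  Over 0–30 N the percent
error decreases from ~0.59% (small-load discretisation bias) to ~0.08% at
30 N, where the deflection is ~45% of the beam length: the discrete bending
law tracks the geometrically nonlinear beam.

## Contact: Hertz–Mindlin with damping and Coulomb friction

Normal force `F_n = (4/3)E*√R* δ^{3/2} − 2√(5/6)|β|√(S_n m*) v_n` with
`S_n = 2E*√(R*δ)` and `β = ln e/√(ln²e + π²)`; tangential force
`F_t = −8G*√(R*δ) δ_t − 2√(5/6)|β|√(S_t m*) v_t`, `S_t = 8G*√(R*δ)`,
capped by `|F_t| ≤ μ|F_n|` with the tangential spring elongation rescaled
onto the cap.  Equivalent properties combine as
`1/E* = (1−ν_a²)/E_a + (1−ν_b²)/E_b`, `1/G* = (2−ν_a)/G_a + (2−ν_b)/G_b`,
`1/R* = 1/R_a + 1/R_b`, `1/m* = 1/m_a + 1/m_b` (a plane contributes zero
inverse radius and mass).  β is stored signed (≤ 0) and applied with an
explicit minus so damping always opposes relative motion.  The tangential
history δ_t accumulates v_t dt while a contact persists, is re-projected
onto the current tangent plane each step, and resets when the contact
breaks.

**No-tension clamp.**  The total normal force is clamped at ≥ 0 (no
cohesion).  Consequence: the effective restitution of a binary collision
exceeds the nominal e at strongly inelastic settings, because the clamp
removes the attractive tail of the damping force at the end of restitution
— e_eff ≈ 0.40 for nominal e = 0.3, ≈ 0.55 for 0.5, ≈ 0.81 for 0.8
(confirmed against a high-accuracy ODE integration of the same clamped
model, which the engine matches to < 2%).  Without the clamp the damping
form recovers e essentially exactly.  The clamp is kept because tensile
tooth–bristle contact is unphysical here.

**Tooth contact query.**  The tooth model is translation-invariant in y,
so sphere-vs-tooth contact reduces to a closed-form 2-D query against the
5-segment boundary of the plate+groove cross-section, using *signed* face
distances: a center exactly on or slightly behind a face still receives
the outward face normal (overlap δ = r − s), and a center inside the solid
is pushed out through its nearest face only.  Face contacts are preferred
over edge/corner contacts and duplicate corner hits merged, so a sphere
never double-counts one surface patch; a sphere in the concave wall–floor
corner legitimately carries two contacts.  The generic bounded-facet
detector in `contact.py` is the reference implementation and the compiled
query is tested against it.

**Neighbor search.**  Bristle–bristle candidate pairs (adjacent bonded
pairs excluded) come from a `cKDTree` Verlet list with 0.9 mm skin,
rebuilt between kernel chunks with a horizon adapted to the fastest
particle.  336 particles make this performance-trivial but it avoids the
O(N²) inner loop.

## Geometry and kinematics

Coordinates: x = stroke direction, y = across the head, z = surface
normal; plate surfaces at z = 0, overlap positive into the surface.

- **Brush**: 42 tufts on a 3 × 14 grid over the 27.5 × 10.2 mm head
  (spacing 1.96 × 3.4 mm), tips initially coplanar.
- **Teeth**: two coplanar plates of equal width separated by a rectangular
  interproximal groove (width 2.4 mm — slightly above the beam diameter so
  tips can enter — depth 3.0 mm), total measured span 28 mm, plate height
  16 mm.  Excluded *apron* plates continue the surface 36 mm on both
  sides: the right one mirrors the auxiliary plate of the reference
  geometry; the left one exists because the stroke-start head position
  (fixed by the crossing constraint below) overhangs the measured span,
  and bristles should ride on a surface rather than slam a model edge.
  Apron contacts exert forces but never deposit measured wear.
- **Stroke**: one forward + one backward translation at constant V with
  instantaneous reversal, total distance L = 56 mm = 2 × the measured
  span.  The head center starts L/5 before the groove midline so that it
  crosses the groove at stroke fractions 1/5 (forward) and 4/5 (backward).
- **Depth**: the head height is set so the *undeformed* tip spheres
  overlap the plate plane by d_z ∈ {r, r/2, r/4}, r = 0.9 mm.  The run
  starts with that overlap present (the prescribed initial condition), so
  the first milliseconds are a violent, strongly damped engagement
  transient; its forces are reported separately from the crossing-window
  statistics.
- Gravity is off by default (bristle weight ≪ contact forces; flag to
  enable).

## Time integration

Semi-implicit (symplectic) Euler: velocities update from current forces,
then positions from new velocities; clamped particles move kinematically.
Chosen over velocity Verlet for simplicity with velocity-dependent
(damping, friction) forces; the collision oracles bound the accuracy
(energy drift < 1% for an elastic collision at dt_crit/50).

- **Timestep**: `dt = 0.1 × 2√(m_min/k_max)` where k_max bounds the
  stiffest interaction — the chain stretching spring EA/l₀ and the Hertz
  tangent stiffness 2E*√(R*δ) at δ = d_z, the largest overlap the
  kinematics enforce.  Default dt ≈ 1.7e-7 s; a full 0.56 s cycle is
  ≈ 3.3 M steps (≈ 2 minutes on one CPU).
- **Background damping**: mass-proportional viscous damping, default
  γ = 10 s⁻¹, suppresses ringing of bristles released from the groove.  It
  is three orders below critical for the tuft bending mode, so quasi-static
  forces are unaffected; doubling or removing it changes total wear by
  < 1%.
- **Quasi-static relaxation** (`relax_static`): the same integrator with
  strong damping (γ = 2e4 s⁻¹, near-critical for the tuft bending mode)
  and a linear load ramp, run until the maximum free-particle speed and
  net-force residual fall below tolerances (defaults 1e-5 m/s, 1e-4 N).
- **Determinism**: no randomness anywhere; identical inputs give
  bit-identical trajectories, force logs and wear maps.  Simulation
  aborts with a diagnostic naming the offending particle if a bond
  degenerates or energies become non-finite.

## Archard wear

Closed form Q = K·W·L/H; per-contact accumulation Q = (K/H) Σ F_n·|v_t|·dt
over every bristle–tooth contact on a measured facet (bristle–bristle
contacts produce no wear).  Each increment bins to the 0.5 mm cell of the
*unfolded* surface (left plate → left wall → floor → right wall → right
plate along u; y along v) containing the contact point; the Hertz contact
patch (≪ cell size) is not smeared.  The v-grid always has an odd cell
count so one cell is centred on the y = 0 symmetry plane; with an even
count, wear deposited by the middle tuft row (exactly on the plane) bins
asymmetrically and corrupts the symmetry score.  **K is not known for
acrylic-on-enamel and defaults to 1**: outputs are "wear volume per unit
K", and every comparative statement (depth/speed ordering, spatial
concentration, symmetry) is independent of K by linearity.  A dragged-tip
oracle checks that a single constant-load pass reproduces K·W·L/H to
< 0.5%.

The summary reports: total Q; the share and per-unit-area density of wear
in the groove band (groove facets + 2 mm of each adjacent plate) versus
the plate interiors; and a top-bottom symmetry score
‖Q − mirror(Q)‖₁ / ‖Q‖₁.

## What the model reproduces, and what it does not

With the tabulated bulk-acrylic properties and the solid 1.8 mm section —
the same stiffness the 30 N cantilever validation anchors — a vertical
tuft pressed 0.9 mm into rigid enamel carries a post-buckling load of
order π²EI/4L² ≈ 45 N.  The simulator accordingly produces per-tip forces
of tens of newtons (crossing-snapshot mean ≈ 42 N, in-groove crossing max
≈ 60 N, engagement transients ≈ 1 kN), **three orders above the published
0.005–0.05 N force scale**, which would correspond to tip deflections of
only ~10 μm and is mutually inconsistent with the same beam stiffness.
Reproducing the small printed forces requires a tuft bending stiffness
about four orders softer (≈ 40 independent filaments), which contradicts
the aggregate-beam parameterisation.  This tension is inherited by the
wear findings:

- **Reproduced**: strict increase of total wear with brushing depth
  (r/4 < r/2 < r at V = 0.1 m/s); top-bottom symmetry of the wear map
  (score ~1e-5); force concentration on the few groove-crossing bristles
  relative to the groove-window maximum vs the engagement-free mean.
- **Not reproduced**: the decrease of wear with brushing speed — for
  quasi-statically sliding stiff tufts Archard wear is Σ F_n·slip ≈ F·L
  with L fixed, so V cancels (observed spread < 1%, not monotone); and the
  per-unit-area concentration of wear in the groove band — steady plate
  sliding under ~42 N/tip dominates, while groove-wall hits are nearly
  normal (little slip, hence little Archard wear).

The synthetic study conditions (geometry, kinematics, material table) are
exactly the configuration above; no field data enters anywhere.  Passing
tests therefore demonstrate internal correctness of the mechanics (force
laws, integrator, wear bookkeeping, validation against the elastica and
closed-form Archard), not fidelity of the published force magnitudes,
which the parameter set itself cannot produce.

## Known limitations

- Tufts are aggregate beams: no filament-level resolution, no bristle
  wear, no end-rounding geometry.
- Flat-plate tooth model: no anatomical curvature, no gingiva, single
  groove; wear does not alter the geometry.
- Scrub stroke only (no Bass/Roll/Fones patterns); instantaneous reversal.
- No toothpaste abrasives, no cohesive/adhesive (JKR/DMT) contact, no
  rolling resistance; tangential slip is translational only.
- The prescribed instantaneous initial overlap produces a strong
  engagement transient; statistics tied to the stroke crossings are
  reported separately from it.
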