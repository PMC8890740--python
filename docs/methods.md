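# Model and methods

`antraft` simulates a floating fire-ant raft as two coupled layers on a
plane: a **structural layer** — a contracting network of nodes
representing the interlocked worker ants that give the raft its shape —
and a **freely active layer** of self-propelled agents walking on top of
it.  Members exchange between the layers: structural ants *unbind* into
the free layer wherever the network grows too dense, and free ants
*deposit* into the water at the raft's edge, extending the network.  The
resulting steady cycle (treadmilling) and its instability — spontaneous
growth of narrow protrusions — are the phenomena the package exists to
study.

## Units

Lengths are stored in ζ, the occupancy length of one structural ant
(ζ = ρ_r^(−1/2) = 1.81 mm for a planar network density ρ_r = 0.304
ants/mm²).  Behavioural radii and reported results use the mean ant body
length ℓ = 2.93 mm (1 ℓ ≈ 1.619 ζ).  Time advances in steps of
Δt = 0.6 s (0.01 min), the time a free ant needs to traverse the mean
spacing of its movement sites at the measured walking speed
v₀ = 0.97 ζ/s.  (The published table also lists ⟨d⟩ = 1.67 ζ, whose
ratio to v₀ is 1.72 s rather than 0.6 s; the printed Δt = 0.6 s is taken
as authoritative and the discrepancy left unresolved.)

## Domain and initialization

Nodes are seeded on a close-packed hexagonal lattice with unit (1 ζ)
spacing filling a square domain, each coordinate offset by
Uniform[−1/6, +1/6] ζ.  Nodes inside a circle of radius 10 ℓ (default;
configurable) are classified structural, all others water; the node
nearest the origin is a permanent anchor that never moves (the numerical
analogue of the anchoring rod in the experiments).  Free agents are
placed on a fraction φ₀ (default 1) of structural nodes with uniform
random headings.  The default domain half-width is 2.5 × the raft radius
so protrusions cannot reach the boundary.

The hexagonal packing density (2/√3 ≈ 1.155 ζ⁻²) slightly exceeds the
density ceiling enforced later (1 ζ⁻²), so the first minutes of any run
show an enforcement transient; the published experiments show the same
early spike in the turnover rates because the raft "was not initiated at
steady state".

## Structural contraction

Every pair of structural nodes within R_r = 1.5 ℓ contracts: the target
separation after one step is d_ij · exp(−d˙ Δt) with d˙ = 1.9 %/min.
Positions relax toward the targets by a damped Jacobi iteration,

    X_i ← X_i − ν⁻¹ Σ_j (d_ij − d_ij_target),

iterated until the largest pair residual is ≤ 5×10⁻⁵ ζ *and* the mean
pair residual is ≤ 10⁻⁵ ζ (a convergence failure within the sweep cap
raises an error).  Two numerical choices matter here:

- **Damping ν.**  The iteration is stable only if ν exceeds roughly half
  the largest eigenvalue of the pair-graph Laplacian (≈ the maximum
  contraction degree, ~18 for the default radius).  The default is
  ν = 16, and ν is raised automatically to 1.05 × the maximum pair
  degree whenever the network is locally denser (for example in the
  jammed phase, below).  A small fixed ν (such as 2) diverges.
- **Warm start and stopping state.**  Because the pair targets are
  mutually consistent, uniform scaling about the anchor solves them
  exactly; by default the iteration is seeded there and converges
  immediately (`relax_warm_start`).  Cold-started Jacobi reaches the
  residual thresholds only after hundreds to thousands of sweeps
  (transporting the smooth contraction mode diffusively from the
  boundary inward) and stops about 2.5% short of the targets; the two
  variants give emergent strain rates within 2% of each other (a
  regression test pins this), so the warm start is a pure efficiency
  choice.  Either way the emergent global strain rate is ≈ d˙; the
  larger non-affine gap between the local and global rates reported for
  the original experiments is not reproduced by any reading of the
  published relaxation rule that we tested.

## Water packing

Water nodes are advected toward the origin with the same rate
(X ← X·e^(−d˙Δt)) so the vacant lattice tracks the shrinking raft, then
repelled from their neighbours (water *and* structural, one-way: the
raft never moves) by a Gaussian pairwise force of width σ = 0.5 ζ and
strength κ/ν = 0.02, applied once per step.  The printed κ/ν is scaled
for one application per step — it balances the per-step advection at
roughly unit spacing; iterating the repulsion to equilibrium instead
dilates the water field beyond the useful packing density and was
rejected.  Forces are truncated beyond μ + 3σ (~1% of the peak).

## Density-triggered unbinding

After contraction, the domain (excluding a 1 ζ-wide off-domain reservoir
band, below) is covered by an axis-aligned grid of 2 ζ cells.  Any cell
holding more than N_p = ρ_d·L_g² = 4 nodes repeatedly loses one member
of its closest pair (chosen uniformly, never the anchor) until it
complies.  A deleted water node is reseeded on the reservoir band; a
deleted structural node unbinds: its ant becomes a free agent on the
nearest vacant structural node (its rider, if any, is relocated first).
If no vacancy exists — the raft is fully jammed, which the default
φ₀ = 1 initial condition guarantees at t = 0 — the deletion is deferred
to a later step rather than failing; the cell stays over-dense until
edge binds open vacancies.

Reseeded water is placed just *outside* the enforcement grid
([hw, hw+1] in each coordinate) because the initial lattice density
exceeds the enforcement ceiling: reseeding into the grid would create a
permanent delete/reseed churn of the same nodes at the boundary.  The
reservoir is advected back into the domain as the interior drains, so
the water population is conserved step by step.

## Free-agent movement

Each step, every moving agent's heading is updated by the Vicsek rule:
the circular mean of the headings of all free agents within R = 0.9 ℓ
(including itself; structural nodes exert no influence) plus noise
uniform on [−πη, πη], η = 0.2.  Paused agents keep their frozen heading
but still enter their neighbours' means.

Movement is constrained to the node lattice.  An agent ranks its
candidate nodes — up to 18 nearest within R_DOF = 2.5 ζ, two hexagonal
neighbour shells — by the angular difference between its heading and
each candidate's bearing (ties: nearer first, then smaller id), discards
candidates beyond the π/2 turning limit, and takes the first eligible
one.  Occupied structural nodes are skipped (volume exclusion).  Agents
are processed in a fresh random permutation; candidate geometry is
frozen at the start of the sub-step while occupancy and node kinds are
live, so earlier movers block or free sites for later ones.  An agent
with no eligible candidate pauses for 2–4 steps (uniform over whole
steps) and then reorients uniformly at random.

## Edge deposition

A free agent *encounters the edge* when its top-ranked candidate is a
water node — a perception cone of roughly ±15°.  Only then is the
deposition rule evaluated, and only if that water node is in contact
with the agent's site (within 1.35 ζ, the nearest-neighbour spacing plus
jitter): the movement range of two neighbour shells is justified for
walking on the raft, not for stepping into open water.  The rule
compares the transmitted self-propulsion along the agent's heading û
with the effective repulsion from the water it can probe:

    A · Σ_σ (û_σ · û)   >   Σ_ω (R/r_iω) (r̂_iω · û)   ⇔  deposit,

where σ runs over the *moving* (non-paused) free agents in contact
(within R, including the agent itself), ω over water nodes within the
probe range R_DOF, and A = f^a/f^Γ is the activity — the single free
parameter, the ratio of an ant's self-propulsion force to its effective
repulsion from water.  The 1/r weighting is the discrete energy-gradient
force, normalized so a water node at the contact radius R contributes
unit weight.  On deposit the water node joins the structural network and
the agent leaves the free layer; one water node is reseeded at the
boundary so the water count is conserved.

Three realization choices here deserve emphasis (all configurable):
evaluating the rule only for head-on encounters, counting only moving
neighbours in the propulsion sum, and restricting deposition to
in-contact water.  Each removes a pathway by which deposition would
otherwise run away at *any* activity (sideways binding through a ±90°
cone; jammed-but-aligned crowds firing the gate; agents leaping onto
isolated water and building one-node spikes whose surrounding water
cancels out of the vector sum).  With them, the model reproduces the
expected activity phases: a jammed, round raft with φ ≈ 1 at low A;
treadmilling at α ≈ δ ≈ 2 %/min with stochastic protrusions in the
experimental-match range A ≈ 1.25–1.47; and rapid conversion of the free
layer (φ ≲ 0.1) with many narrow protrusions above A ≈ 2 — the
behaviours the acceptance tests measure.

## Per-step pipeline and reproducibility

Raft mode: Vicsek update → contraction → water packing → density
enforcement → agent stepping → recorders.  Free-flow mode (used to
calibrate R and η against the free-ant trajectory persistence length)
runs only Vicsek + stepping on a static, fully structural, periodic
hexagonal lattice.  All randomness flows through one counter-based
generator seeded explicitly; draws occur in a documented order, so a
(config, seed) pair reproduces bit-identically on one platform.  Node
slots of deleted nodes are compacted away periodically; persistent
labels keep trajectories traceable across compactions.

## Observables

- **Strain rate ε̇**: for every structural node alive through a
  measurement window, the inward radial speed toward the anchor from its
  first-to-last displacement; ε̇ is the least-squares slope of speed
  against time-averaged radius.  Exact on synthetic exponential flows.
- **Turnover rates α, δ**: binds (unbinds) per time bin divided by the
  bin-mean structural population — exact bookkeeping of the event log.
- **Surface excess S = C/(2√(πA_r))** with C the number of perimeter
  structural agents (those with water within 1.6 ζ) and A_r the total
  structural count.  S ≈ 0.93–1 for lattice discs; 1 for a perfect
  circle.
- **Velocity order parameter φ = |⟨v⟩|/⟨|v|⟩** over per-step agent
  displacements.
- **Persistence length l_p**: exponential fit of the tangent correlation
  ⟨cos Δθ(s)⟩ over path-length lags up to 10 ζ, validated against the
  closed form for independent heading increments.
- **Protrusions**: structural occupancy is rasterized at 1 ζ, closed
  with a radius-1 disk, and skeletonized (medial axis with distance
  transform).  A skeleton branch is a protrusion iff its local width
  (twice the distance transform) stays below 10 ℓ — half the free-ant
  persistence length — its arc length is at least its mean width, it
  lies mostly outside the morphological opening of the body at that
  width (rejecting interior skeleton spurs), and its tip stands off from
  the opened bulk by at least 3/4 of its mean width (rejecting the
  shallow wedges left at wide-lobe junctions).  Width W is the mean
  local width; the growth rate V projects the tip displacement of a
  base-matched protrusion onto the tip tangent, smoothed over 1-min
  windows.  The published measurements were manual; this raster/skeleton
  pipeline is an algorithmic proxy, and tolerances on W and V are read
  accordingly.
- **Tip radius R_κ**: the raft boundary contour (marching squares on the
  raster) is smoothed over 1 ℓ for fitting; convex/concave segmentation
  uses a more heavily smoothed geometry (5 ℓ) because raster stair-step
  noise otherwise flips the curvature sign on gently curved boundaries.
  The convex segment around a tip is cropped at the flanking inflections
  and Pratt-fitted; one or two remaining points map to 0.5 ℓ and 1 ℓ
  (single- and two-agent tips).

## Known limitations

- The contraction's realized strain rate depends on the relaxation's
  stopping state, which the residual thresholds only partially pin down;
  different (stable) ν values give the same answer, but a fundamentally
  different solver would not.
- In the jammed phase the density ceiling cannot be enforced (no
  vacancies), so the network slowly densifies and the relaxation becomes
  more expensive; long low-activity runs are the slowest configurations.
- Raster-based shape metrics carry ±1 ζ discretization error; surface
  excess inherits the coastline-resolution caveat of the original
  measurements and is best read comparatively.
- Agents have no body aspect ratio, cannot walk over one another, and
  there are no external cues or gradients.
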