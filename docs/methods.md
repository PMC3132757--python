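# Methods

`podosim` simulates the *in vitro* expansion of mesenchymal stem cells
(MSC) as an off-lattice, individual cell-based model in which each cell is
an elastic, compressible sphere on an adhesive substrate, carrying a
variable number of explicit, force-generating podia.  Podia drive all
migration; density-dependent regulation of proliferation, migration and
morphology produces contact inhibition and the characteristic nematic
cell–cell alignment of dense fibroblastoid cultures.

## Units

Internally everything is expressed in µm, min and nN.  Published
parameter values in mixed SI units (µN/m, kPa, Ns/m³, Ns/m, 1/d) are
converted on input and reproduced on output; in these units the key time
constants are near unity (podium retraction time γ_p/k ≈ 11.7 min, one
expected podium update per minute).

## Cell bodies

A cell body is a sphere of radius R with planar centre position and a
centre height z above the rigid substrate plane.  Contacts flatten the
sphere: a cell–cell contact at centre distance d < R_i + R_j removes the
spherical caps on either side of the geometric intersection plane, with
contact-circle radius r_c² = R_i² − x_i², x_i = (d² − R_j² + R_i²)/(2d);
the substrate contact removes the cap below z with adhesion radius
a_is = √(R² − z²).  The actual volume V is the sphere volume minus all
caps; the target volume V_t is the cell's regulatory growth variable.

The per-cell body energy has three parts:

* adhesion: −ε_cs·A_is for the substrate, and −ε_cc·π·R_eff·g(δ) per
  cell–cell contact, where R_eff = R_iR_j/(R_i+R_j), δ is the overlap and
  g is the contact gauge described below;
* deformation (Hertz): (8/15)·E*·√R_eff·δ^{5/2} with
  1/E* = 2(1−ν²)/E for cell–cell contacts and (1−ν²)/E against the rigid
  substrate (R_eff = R there);
* compression: (K/2)(V − V_t)²/V_t.

Forces on centres and radii are the exact analytic gradients of the
population energy (pair terms counted once); Newton's third law holds by
construction and is verified against finite differences in the tests.

### The cell–cell adhesion gauge

The adhesion energy per contact uses the elastic (Hertz) contact zone
A = π R_eff δ rather than the larger geometric intersection circle, with a
quadratic onset over the first δ_m = 2 µm of overlap:
g(δ) = δ²/(2δ_m) for δ ≤ δ_m and δ − δ_m/2 beyond.  The onset represents
adhesion-bond density building up as a fresh contact matures.  Its
practical consequence is a pull-off force of ≈1.3 nN, below the podium
protrusion force of 2.5 nN: a migrating cell can detach from a neighbour,
daughters can separate after division, and colonies disperse — while
resting contacts remain cohesive, equilibrating at ≈2.5 µm overlap.
Without the onset the pull-off force (≈4.5 nN for the Hertz zone, ≈9 nN
for the intersection circle) exceeds anything the podium apparatus can
exert and every contact becomes permanent; colonies then freeze at a few
dozen cells, which contradicts the observed expansion dynamics.  The
geometric intersection circle is retained wherever it is genuinely
geometric: cap heights, actual volumes, friction areas and the reduced
surface area.

### Height balance

The centre height is not a dynamic variable.  Each step it is re-solved
quasi-statically per cell by bisecting the normal-axis force balance
(substrate adhesion pulling the centre down versus substrate Hertz
repulsion and compression pushing it up) to 10⁻⁶ µm.

## Podia

A podium is a cone in the substrate plane: base at the cell centre with
the adhesion radius a_is, a spherical tip of radius 0.6·a_is, and length
L measured from a_is/2 to the tip centre.  Its life cycle:

1. **Generation.**  Per cell, podium-count update events arrive as a
   Poisson stream at λ = 1440/d (≈1/min).  An event generates a podium
   with probability clamp(g₀(n_off − n_act − ½), 0, 1), where n_act is
   the active count, n_off the regulated offset (3.5 low density, 2.5
   high) and g₀ = 0.05 the generation acceptance scale.  A new podium
   starts active with length a_is/2 (tip at the body edge).  The half
   shift zeroes churn exactly at the regime count (3 low / 2 high), so
   resting spindles keep their podia; the small g₀ sets the regeneration
   time of a lost podium to tens of minutes, which is what makes cells
   migrate persistently (see below).
2. **Angles.**  Directions are drawn by rejection sampling: uniform
   proposals are rejected against the nearest angular neighbours on
   either side with probability exp(−N_p·|Δθ|/c_a) per side (N_p = total
   podium count, c_a = 3 rad), OR-combined; after 100 rejections the
   least-rejected proposal wins.  For cells holding two podia the
   accepted angle to the nearest podium has its histogram mode near 70°,
   matching measured pseudopod outgrowth statistics.
3. **Elongation.**  The tip obeys γ_p·dL/dt = F_p·[active] − k·L along
   its axis; the update uses the exact exponential propagator (the
   equation is linear), so the maximum length F_p/k = 25 µm and maximum
   tip speed F_p/γ_p ≈ 2.14 µm/min are reproduced to machine precision.
   Tips adhere to the substrate: when the body moves, each tip keeps its
   laboratory position and angle/length are re-derived from the new base.
4. **Inactivation.**  Two OR-combined channels: the λ-stream inactivates
   with probability clamp(n_act − n_off, 0, 1) per podium (shedding
   excess podia), and an independent rate r_ind (2/d at low density, 0 at
   high) inactivates podia at random.  An inactive podium's protrusion
   force is permanently off; it retracts under the spring.
5. **Elimination.**  Inactive podia shorter than the adhesion radius are
   deleted (hidden below the body).  A long trailing podium persists
   while the cell drags it.

Traction k·L·p̂ from every podium (active or trailing) enters the body
force balance.  The closed-form single-cell steady states used as test
oracles: one active podium gives v = F_p/(γ_p + Γ_b) and
L = Γ_bF_p/(k(γ_p + Γ_b)) with Γ_b = γ_cs·A_is + γ_v; an additional
trailing podium reduces the speed to F_p/(2γ_p + Γ_b).

### Migration phenotypes

A cell resting with 2–3 stretched podia is force-balanced.  Losing a
podium (r_ind, or the division program) leaves an asymmetric
configuration that pulls the body at roughly the single-podium
equilibrium speed (≈0.6–0.8 µm/min) until the complement is regenerated
(~20–40 min at g₀ = 0.05).  Low-density cells therefore alternate
ballistic episodes with resting, producing a ballistic-to-diffusive MSD
crossover; high-density cells (r_ind = 0, n_off = 2.5) freeze as 2-podia
spindles with podium lengths near the 25 µm maximum.

## Contact guidance

After the independent podium updates, overlaps between cells are resolved
pairwise.  The axis (mid-line) of a moving podium, inflated by its tip
radius, is tested against the body discs and podium cones of neighbouring
cells; an overlapping podium is rotated about its base by the minimal
angle that clears the obstacle, length preserved.  Which of a pair moves
follows a global precedence scheme (higher precedence always moves; small
overlaps move the intersecting podium; crossing mid-lines move the podium
whose tip is closer to the crossing; head-on ties move the shorter
podium, exact ties the lower (cell id, podium index); a moved podium
takes precedence one above its obstacle and resets to one when clear;
switched-off podia are never shifted).  A podium intersecting several
distinct cells is resolved against one obstacle at a time in a fixed
record order, re-verifying each overlap before moving — stalling such
podia (or their owner cells) instead freezes confluent cultures entirely.
Unresolvable tangles in dense culture leave residual overlaps, as real
confluent cultures do.

Microgrooves are handled like podia that are never moved: with
probability p_groove = 0.15 per podium per step, a podium whose mid-line
crosses a groove edge — and whose tip has not already climbed inside the
groove — is rotated to the groove axis, choosing the sense that minimises
the rotation.  The skip rule lets cells cross grooves.

## Proliferation

Five phases with four checkpoints.  Daughters start in phase 0 with half
the parent target volume and a radius matching it; once the actual volume
catches up (within lag_frac = 0.1) they enter phase 1 and grow V_t in
stochastic increments (rate m_inc = 20/d, quantum = rate/m_inc = 60 µm³
at low density).  Compressed cells (actual volume lagging by more than
lag_frac) rest in phase 2.  At V_t = V_max = 2·V₀ ≈ 898 µm³ with the
actual volume caught up, cells enter phase 3: growth stops, podia are
inactivated and retract.  When the last podium is deleted (phase 4) the
cell divides: daughters are placed just touching, symmetrically about the
parent centre along the consensus podium orientation recorded at phase-3
entry (uniform if none).  Each daughter remembers its outward direction
and sprouts its *first* regrown podium along it, so sibling pairs
elongate end-to-end and separate — the division figure's "podia align to
each other".  There is no cell death.

## Density regulation

The neighbour count n of a cell is the number of other cells whose body
disc lies within d_nn = 5 µm of the cell's footprint (body disc or podium
cones) or vice versa.  Podium–podium proximity alone does not count: long
podia sweeping past each other do not crowd the bodies, and counting them
saturates the regulation in any spread colony.  Three ramps (constant
plateaus with a linear transition) map n to the growth rate (1200→0
µm³/d between 4 and 5 neighbours), r_ind (2→0/d between 1 and 3) and
n_off (3.5→2.5 between 1 and 3).

## Time stepping

Each dt = 1 min step executes: (1) podium tip dynamics, generation,
inactivation, elimination, overlap resolution, groove alignment; (2) body
forces and the coupled over-damped velocity solve (sparse LU on the
symmetric friction matrix; cell–cell friction couples cells through their
shared contact areas), explicit Euler with at most two force evaluations
per step and a 1 µm per-cell displacement cap that tames stiff
post-division transients; confinement projects centres back onto the
boundary circle; (3) radius velocities γ_R·S̃·Ṙ = F_R (S̃ the
cap-flattened surface area) and the quasi-static height re-balance;
(4) neighbour counts (refreshed every 3 steps — the ramps vary on the
hour scale — and immediately after divisions), regulation, target-volume
growth, phase transitions, divisions.  A single seeded random stream is
consumed in fixed order (cells ascending, podium slots by index), making
runs bit-reproducible; a speed above 50 µm/min aborts the run as numeric
divergence (podium-driven speeds top out near 2 µm/min and division
transients at a few µm/min).

## Metrics

* Consensus orientation: the axis φ ∈ [0, π) maximising Σ_m|cos(φ−θ_m)|,
  solved exactly piecewise (breakpoints θ_m ± π/2; per-piece stationary
  points); ties resolve to the smallest angle.
* Order parameter S(d) = ⟨cos 2Δφ⟩ over cell pairs binned by centre
  distance (5 µm bins); S* is the unweighted mean over occupied bins up
  to 50 µm.  S is 1 for aligned, 0 for disordered populations, invariant
  under global rotations and orientation flips.
* Mean population radius ⟨|r_i − r_c|⟩ and aspect ratio
  ⟨|y_i − y_c|⟩/⟨|x_i − x_c|⟩, computed on cells inside the configured
  evaluation frame where one is set.
* MSD kinetic exponent β(t) = d ln msd/d ln t by central differences on
  log-spaced lags, ensemble-averaged over tracks and time origins.

## Image pipeline

Synthetic micrographs are rendered from states (bright bodies and podium
cones, additive Gaussian noise).  Segmentation is two-cluster fuzzy
c-means on intensity (membership exponent 2, tolerance 10⁻⁵, ≤300
iterations, deterministic quantile initialisation), hard assignment to
the brighter cluster, connected components, and a 50 px minimum size.
Orientation is the principal axis of the second central moments; nearly
isotropic regions (axis ratio < 1.05) are dropped.  The closed loop
render → segment → orient recovers model consensus orientations of
spindle cells within 5°.  Touching-cell instance splitting is out of
scope, so segmentation-based statistics in confluent cultures
overestimate disorder relative to the model's own orientations.

## What the synthetic world does and does not establish

The generator's defaults are the published parameter table plus the
documented gap-filling constants (g₀ = 0.05, δ_m = 2 µm, lag_frac = 0.1,
V_max = 2V₀, cone tip fraction 0.6, p_groove = 0.15, dt = 1 min).  Green
tests establish internal consistency with the stated mechanics and the
published statistics they encode (angle mode, podium length scale, yield
ordering between substrates), not agreement with any new experimental
data: real MSC cultures have heterogeneous cell sizes, 3D overlap at
confluence, and imaging artefacts that the model deliberately omits.

## Numerical choices

Capsule distances between footprint primitives (convex hulls of two
discs) are computed by alternating exact 1-D minimisation of the convex
objective, warm-started from the segment–segment solution; classification
against d_nn short-circuits through analytic bounds.  Clearing rotations
use the closed-form blocked wedges of the obstacle's end discs with a
bisection fallback to 10⁻³ rad.  The velocity system is strictly
diagonally dominant and solved exactly (sparse LU); the momentum balance
Σ(drag) = Σ(applied) holds to solver precision.  Groove membership uses
closed intervals so boundary points classify deterministically.

## Known limitations

Strictly 2D (no multilayer growth), no cell death, no nutrient or oxygen
fields; substrate is rigid and flat (no stiffness sensing, no groove
depth); the pairwise guidance scheme leaves residual overlaps in crowded
regions, and the nematic order it produces at the miniature test scales
(S* ~ 0.1 in a 150-µm dish) is weaker than full-scale dense cultures
reach -- the order statistics are therefore asserted comparatively
(regulated vs unregulated growth) rather than absolutely; width
dependence of the groove alignment probability is exposed as a parameter
rather than derived; population counts at matched times vary between
seeds by design (stochastic generation, inactivation, growth increments
and division axes).
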