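# Methods

## The model

Both tissues are represented by point particles confined to a sphere of
radius R = 592 μm (the fitted egg-surface radius), integrated with
overdamped, unit-mobility forward-Euler steps: velocities equal forces,
appropriate for the inertia-free cellular regime. After every step each
particle is re-projected radially onto the sphere; forces are projected to
the local tangent plane before stepping.

**EVL.** The enveloping layer enters through the vertices of its polygonal
cells. Two spring families connect them, both harmonic with elastic
constant U₀ and rest length equal to the length at mesh construction:
*edge springs* between consecutive vertices of a cell cycle, and
*opposite-vertex springs* across each cell, which penalise over-expansion
of individual cells while the tissue stretches. For a cycle of m vertices
the opposite pairs are (k, k+⌊m/2⌋); odd cycles pair each vertex with both
nearest-to-opposite partners at half weight so the across-cell stiffness
matches the even case. Bulk vertices are passive (springs only). Margin
vertices — the free vegetal border — are instead driven at constant speed
V₀ along their meridians toward the vegetal pole, the epibolic boundary
condition that stretches the network and drives spreading; a margin
vertex reaching the vegetal pole is clamped there (its meridian direction
is undefined).

**DCL.** Deep cells are soft spheres of radius ~15 μm. Per step, the
displacement is

dt · (F_rep + F_att) + drag · Δr_EVL + ξ

* *Repulsion*: for overlapping pairs (centre distance d < r_i + r_j), a
  force U₁·(r_i + r_j − d) along the centre line — a linear overlap
  penalty that keeps cells from interpenetrating without long-range
  interaction.
* *Border attraction*: potential U(d) = −U₂·C_att·exp(−d²/(2a₂²)) with d
  the geodesic distance to the nearest EVL cell-border arc; the force
  pulls toward the closest border point. This encodes the short-range
  attraction of deep cells to the stiffer, high-tension EVL cell borders.
* *Drag*: Δr_EVL is the per-step displacement of the substrate under the
  particle, interpolated with barycentric weights over the enclosing
  triangle of the Delaunay triangulation of all EVL vertices, built on
  the azimuthal-equidistant projection about the animal pole. `drag`
  scales it in [0, 1]: 1 is full adhesive coupling, 0 a detached cell.
  Particles that fall just outside the triangulation (beyond the margin)
  fall back to inverse-distance weights over the three nearest vertices
  and are counted.
* *Noise*: zero-mean Gaussian in the two tangent directions with
  per-component variance 2·D_n·dt, realising autonomous random motility
  with diffusion coefficient D_n.

**Division.** Each deep cell divides exactly once, at a time drawn
uniformly from a configurable window (default the middle 80% of the run),
emulating one asynchronous division round that doubles the population.
Daughters keep (1/2)^(1/3) of the parent radius (volume conservation) and
are placed ± half a parent radius apart along a random tangent direction —
the placement geometry is not constrained by data; only the radius rule
and the single-division restriction are.

## Parameters, units, defaults

| name | meaning | default | unit |
|------|---------|---------|------|
| U₀ | EVL spring constant | 0.1 | min⁻¹ (velocity per μm strain) |
| V₀ | margin speed | 0.25 | μm/min |
| U₁ | DCL repulsion amplitude | 0.2 | min⁻¹ |
| U₂ | border-well amplitude | 0.3 | dimensionless (see C_att) |
| a₂ | border-well width | 15 | μm |
| σ | noise amplitude | 2×10⁴ | dimensionless (see below) |
| drag | EVL–DCL coupling | 1.0 | — |
| dt | integration step | 0.5 | min |
| frame_interval | output cadence | 10 | min |
| R | egg radius | 592 | μm |

Two declared conversion constants anchor the dimensionless amplitudes:

* `SIGMA_TO_D` = 2.6×10⁻⁵ μm²/min per σ-unit, so σ = 2×10⁴ gives
  D_n = 0.52 μm²/min (31.2 μm²/h) — an rms autonomous step of ≈4.6 μm per
  10-min frame, the scale of observed deep-cell steps. σ is kept as the
  model's native amplitude so the fitted optimum is quoted on its scale.
* `ATTRACTION_SCALE` (C_att) = 15 μm²/min per U₂-unit, giving the default
  well a depth of 4.5 μm²/min ≈ 8.7 × D_n. In the overdamped-Langevin
  picture the stationary distribution weights the well by
  exp(depth/D_n), so this ratio concentrates cells within ~a₂ of borders
  without freezing their motility — the regime the tracked embryos show
  (border-hugging cells that still exchange positions).

V₀ = 0.25 μm/min reproduces a margin advance of ≈30% → 60% epiboly over
24 h on a 592 μm egg. a₂ = 15 μm places the attraction zone well inside
the ±40 μm preferential band observed around borders. U₀ and U₁ are
stability-limited defaults (U·dt ≪ 1); the EVL relaxes quasi-statically
behind the advancing margin.

## Geometry

* Sphere fitting is the linear least-squares solution of
  x²+y²+z²+ax+by+cz+d = 0; centre (−a/2,−b/2,−c/2), radius
  √(a²/4+b²/4+c²/4−d). The package exposes both per-dataset refitting and
  the fixed 592 μm radius.
* Angles use atan2(|p×q|, p·q), stable near 0 and π; spherical polygon
  areas sum signed Van Oosterom–Strackee triangle solid angles fanned from
  the first vertex (the spherical shoelace), orientation-independent by
  absolute value.
* Point-to-border distances treat each cell edge as a great-circle arc;
  the perpendicular-foot case and the endpoint case are distinguished by
  an in-plane test. A precomputed `ArcSet` turns repeated queries into
  three matrix products; it is verified against the direct per-arc
  implementation in the tests.
* Drift removal normalises each tracked cloud to unit directions (growth
  on the egg is radial/tangential scaling of directions, so normalisation
  isolates rotation) and solves rotation-only orthogonal Procrustes
  (Kabsch) against the first frame, then aligns the animal–vegetal axis
  to +z. Exact under isotropic growth + rotation; verified to 0.1° on
  that calibration scenario.

## Analytics conventions

* MSD pools squared 3D displacements over all sliding windows of all
  tracks (lags 1–25 frames); per-track averaging is available but pooling
  is the default.
* D = slope/4: motion is confined to the locally flat 2D surface, so two
  degrees of freedom contribute. Users preferring the 3D convention can
  divide the slope by 6 instead.
* Nearest-neighbour distance takes k as an explicit parameter (both k = 3
  and k = 6 are conventional); distances are geodesic.
* The distance-to-border histogram uses 5 μm bins on [0, R_c] with the
  analytic uniform baseline p(d) = 2(R_c−d)/R_c² for an equivalent cell
  radius R_c (default 120 μm).
* Epiboly index = 100·(R − z̄_margin)/(2R): 0% at the animal pole, 50% at
  the equator, 100% at the vegetal pole.
* Track linking is greedy nearest-centroid (candidates taken in order of
  increasing distance), faithful to the original pipeline; optimal
  assignment is used only as a test oracle. QC flags (speed > 35 μm/frame,
  area change > 200% EVL / 50% DCL, appearance, disappearance) annotate
  rather than drop links.
* Trajectory decomposition defines autonomous = total − advected per
  frame pair, with the advected part from one of three deformation
  models; the Delaunay-barycentric model (weights recomputed every frame)
  is the default and shows the lowest error on both analytic scenarios.
  The "two closest vertices" model aggregates by inverse-distance weights
  (plain mean available); the 2D projection is azimuthal equidistant
  about the animal pole, which preserves distances from the pole and
  keeps distortion small over the analysis cap.

## Morphometrics

λᵢ are square roots of the spacing-aware second-moment eigenvalues —
lengths, not variances — so elongation 1−λ₂/λ₁ and flatness 1−λ₃/λ₂ stay
in [0, 1]. Connectivity is 8-neighbour in 2D and 26-neighbour in 3D.
Solidity is area over convex-hull area. The protrusion detector consumes
body and membrane masks directly (the upstream segmentation is out of
scope); a protrusion's base is the centroid of its body-contact pixels.
The classifier cascade is applied in the fixed order: area > 1.1 μm²,
then eccentricity > 0.97 → elongated, else solidity > 0.65 → round, else
multiple elongated.

## Fitting

The EVL target is the scale-normalised sum of squared per-cell area
differences between simulation and reference. The DCL target sums, over
four statistics (six-nearest-neighbour distance per frame, border-distance
pdf, MSD curve, per-frame step-length pdf), the discrepancy
‖s−r‖²/((‖s‖+‖r‖)/2)², which is symmetric and dimensionless; weights
default to equal and are configurable. Simulation noise inside the
objective uses common random numbers (a fixed per-evaluation seed), making
the objective deterministic for the Nelder–Mead simplex; restarts sample
uniformly within bounds. Landscape sampling reports min–max-normalised
target values over a parameter grid.

For synthetic work, simulated and reference cells correspond by
construction (same seed rebuilds the same initial mesh and population);
position-based matching of real datasets is out of scope.

## Synthetic data: what it does and does not emulate

The generators reproduce the study conditions — 50–60 polygonal EVL cells
(Lloyd-relaxed Voronoi on the animal cap, shared vertices, convex simple
cycles), 100–120 deep cells placed uniformly under the cap and doubling
once, 10-min imaging cadence, 592 μm egg — and provide exact ground truth
(generating parameters, analytic deformation fields, known protrusion
shapes). They do not emulate segmentation noise, confocal depth artefacts,
EVL cell fusion/extrusion/failed cytokinesis, z-noise in centroids, or
biological heterogeneity of motility between cells. Passing tests
therefore certify the algorithms and the model's internal consistency,
not robustness to real imaging error.

Validation problem sizes: the parameter-recovery experiment uses the
full-scale synthetic embryo (55 EVL cells, 110→220 DCL cells) over 60
frames; the spreading-statistics run uses 100 frames; diffusion recovery
uses 300 tracks of 100 steps. These sizes were chosen so each quantity's
sampling error sits comfortably inside the tolerance it is checked
against.

## Numerical choices and degeneracies

* dt = 0.5 min with per-frame refresh of the Delaunay triangulation and
  border `ArcSet` (the EVL moves ≪1 μm per step, so within-frame geometry
  drift is negligible). Halving dt changes deterministic trajectories at
  first order, as expected for Euler.
* A step moving any particle farther than 0.1·R aborts the run with a
  diagnostic rather than silently re-projecting a blow-up.
* Coincident spring endpoints, degenerate triangles, empty polylines,
  sub-4-point sphere fits and coplanar clouds raise errors; zero path
  length (directionality) and all-zero MSD return NaN with a warning
  rather than raising, since they occur in legitimate stationary data.
* Greedy linking of an empty frame flags all active tracks as
  disappearing.

## Known limitations

* The exact functional forms of the published force terms are not fully
  specified in prose; the harmonic/soft-sphere/Gaussian forms here are
  the simplest consistent choices, and each sits behind its own function
  so alternates can be swapped.
* Whether bulk EVL vertices carry active forces besides springs is
  unknown; they are passive here.
* The frame-level trajectory decomposition leaves a small O(dt)
  discretisation residue when applied to sub-step-advected simulation
  output (~5–10% of path length in the advection limit).
* Barycentric interpolation systematically underestimates the deformation
  of an expanding sheet between vertices; model comparison reports this
  as a non-zero floor for all three deformation models.
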