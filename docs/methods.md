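# Methods

## Model

Cortical folding is modeled as differential growth of a two-layer soft solid.
The tissue is a compressible neo-Hookean material with strain energy density

    W(F) = mu/2 [ tr(F Fᵀ) J^{-2/3} - 3 ] + K/2 (J - 1)^2,   J = det F,

with shear modulus `mu` (the stress scale; nondimensional default 1) and bulk
modulus `K = 5 mu`, a modestly compressible setting: volume changes are
penalized but not forbidden.  Growth enters multiplicatively, `F = Fe G`;
stress and energy are always evaluated on the elastic part `Fe = F G⁻¹`.  The
growth tensor stretches the two directions tangential to the local reference
surface normal `n`:

    G = g_eff (I - n nᵀ) + n nᵀ,        det G = g_eff²,

so `g²` is the areal expansion of cortex relative to white matter.  The
gray/white transition is graded by the indicator

    theta(y) = 1 / (1 + exp(10 (y/T - 1))),

where `y` is the element's reference depth below the outer surface and `T`
the cortical thickness; the effective tangential stretch is
`g_eff = 1 + theta (g_schedule - 1)` (linear in stretch — the simplest
monotone blend; the underlying model grades growth only through theta without
prescribing the blend).  Growth is ramped linearly in stretch from 1 to the
target (g ≈ 1.9 for the normal configuration) and elements under the
no-growth masks (central ball, bottom slice) always carry `g_eff = 1`.

The growth axis `n` of each element is the outward normal of its nearest
reference boundary triangle, fixed at the start of a simulation (growth
directions do not convect with deformation).  For the slab fixture the
"surface" is the top face only: the lateral walls are artifacts of the
fixture, not tissue boundary.

## Discretization and solver

The energy is discretized on linear tetrahedra.  Forces are exact gradients
of the discrete energy.  Three standard ingredients make linear tets usable
here:

* **Nodal pressure.**  The volumetric term `K/2 (J-1)²` is evaluated on
  nodal-averaged volume ratios `J̄(a) = Σ V_ref J / Σ V_ref` over the tets at
  each node (quarter-volume lumping), which removes the checkerboard locking
  of linear tetrahedra.  The isochoric term stays elementwise.
* **Inversion handling.**  Elements near or past inversion are routed through
  a rotation-consistent signed SVD (`det U = det V = 1`, smallest singular
  value carries the sign of `det F`); singular values are clamped at the
  floor 0.05 before stress evaluation, so forces stay finite, continuous
  across `det F = 0`, and act to restore positive volume.  A cheap exact
  bound (`sigma_min >= 2 J / tr(FFᵀ)`) gates the SVD so it only runs where
  the clamp could activate.
* **Penalty self-contact.**  Each surface vertex within the cutoff of a
  topologically non-adjacent surface triangle receives a linear penalty force
  `k (cutoff - d)` away from the triangle, with the opposite force spread on
  the triangle nodes by barycentric weights.  Candidates come from a uniform
  spatial hash; the candidate list is detected within 1.5x the cutoff and
  cached while no surface node has moved more than 0.25x the cutoff.
  Defaults: cutoff 0.4x the mean surface edge, stiffness 40 mu x edge.

Quasistatic equilibria are found by damped explicit dynamics: semi-implicit
Euler, `v <- (v + dt f/m)(1 - c dt)`, `x <- x + dt v`, with light viscous
damping (`c dt = 0.02` in scenario runs) plus kinetic-energy resets (zeroing
velocities at each kinetic-energy peak, i.e. dynamic relaxation), which
converges far faster than heavy viscous damping alone.  Growth is applied in
increments, each followed by relaxation until the peak nodal residual drops
below a tolerance expressed in units of `mu h²` (h = median element
altitude).

Time is not physical.  Lengths are in units of the brain size R, stresses in
units of mu, nodal density 1.  One global stable time step
`dt = 0.3 h sqrt(rho / (K + 2 mu))` is used for the whole mesh; elements
smaller than the stable size for that dt (the radially graded interiors, the
thin cortical shells) are selectively mass-scaled, which changes transients
but not the equilibria a quasistatic study cares about.

## Synthetic geometry

Reference meshes for the real problem are derived from MRI and are not
redistributable, so the package generates deterministic proxies:

* **Ellipsoidal brain proxy.**  Concentric icosphere shells joined by prisms
  split into conforming tetrahedra (quad diagonals chosen through the
  globally smallest vertex index), radially graded — fine near the surface so
  the cortical band is resolved, coarsening inward, with a center fan.
  Optional invaginations (steep-walled sqrt-raised-cosine radial dents,
  depth as a fraction of R) mimic pre-existing sulci, and a smooth seeded
  radial noise field of amplitude 0.01 R breaks symmetry the way natural
  anatomical asymmetry does.  A perfectly symmetric proxy would sit on
  unstable equilibria indefinitely.
* **Flat bilayer slab.**  A Kuhn-subdivided hex lattice, bottom face fixed,
  lateral faces on rollers (zero normal displacement) so tangential growth of
  the top layer is fully laterally confined.  An optional smooth seeded
  jitter of the interior nodes (0.3x the edge length, tangential on all
  clamped faces) provides the symmetry breaking that a perfect lattice lacks:
  the flat state of a regular lattice is an exact — if unstable — equilibrium
  and would never buckle.

The reference depth `y` is the exact distance from each element centroid to
the boundary surface (full scan over boundary triangles with a
centroid/circumradius pruning bound; an independent exhaustive scan
cross-checks it in the tests), computed once in the reference configuration
and never updated during deformation.

## Scenarios and the desk-scale study conditions

Presets carry the model constants — `K/mu = 5`, `R/T = 10`, `g = 1.9` — and
the malformation factors: thickness x 1/4 (global or in a 30 degree lateral
patch) and x 2, growth-excess x 1/4 and x 3/4 with thickness x 1.5.
"Reducing the growth rate to x of the original" multiplies the excess stretch
`(g - 1)` by x, so factor 0 yields no growth; scaling `g` or `g²` instead is
available as a configuration switch.

The reference simulations behind these scenarios use imaged meshes with over
a million elements; the package's trend experiments are deliberately
desk-sized and qualitative:

* **Ellipsoid trend runs** (`desk_scenario`): unit sphere, `R/T = 3`,
  tangential edge 0.15 (icosphere subdivision 3, ~20k tets) for runs whose
  cortex is at least the reference thickness; runs containing a
  quarter-thickness cortex are meshed at an edge ≤ 0.8 x that thickness
  (subdivision 4, ~1.3 x 10⁵ tets) and run a shorter schedule (they fold
  early at small wavelength; the localized-thinning case keeps a longer one
  because a patch embedded in a non-folding matrix folds later than a
  globally thin cortex).  The coarse runs use 20 growth increments with a
  300-step relaxation budget each plus a 1500-step final relaxation.
  `R/T = 3` is a compromise: at the reference `R/T = 10` even the
  unperturbed cortex is unresolvable at desk scale, while at `R/T = 2.5` the
  surface curvature visibly suppresses folding of the normal configuration.
* **Slab wavelength runs** (`desk_slab`): a laterally confined quasi-2D
  strip, 4.5 long and 0.75 deep, cortex `T = 0.25` scaled by the thickness
  factor, each case meshed at one third of its own cortical thickness
  (5.8k tets for `T`, 23k for `T/2`) and relaxed deeply (30 increments x 400
  steps + 3000 final).  Both ingredients matter: a 2-element cortex is
  numerically too bend-stiff and folds too wide, and an under-relaxed run
  freezes the perturbation spectrum instead of the mechanically selected
  wavelength.  The wavelength is the median spacing between deep sulci
  (connected intervals of the y-averaged material-coordinate top profile
  descending below 35% of the deepest trough); both thicknesses then fold at
  ~2.5-3 T and the `T : T/2` wavelength ratio lands close to 2.

What desk scale does and does not show: the runs reproduce the *mechanism*
(sulcification of a growing constrained layer, wavelength proportional to
cortical thickness, folding strength increasing with growth) and the
*orderings* across malformation scenarios; they do not reproduce fold counts,
positions, or spectra of real brains, which depend on the real geometry and
resolution.  Fold counts at desk scale are mesh-limited for the
quarter-thickness cortex (its natural wavelength is barely resolved, so
tightly packed folds partially merge into sulcal networks), which makes the
counts conservative — under-resolution reduces, never inflates, the thin
case's count advantage.

## Morphometrics

Curvature uses the standard discrete operators: angle-defect Gaussian
curvature and cotangent-Laplacian mean curvature on Voronoi-mixed areas,
signed so convex regions are positive (outward normals).  Koenderink's shape
index `s = (2/pi) arctan((k1 + k2)/(k1 - k2))` maps domes to +1 and pits to
-1; umbilics take `sign(H)` and flat umbilics 0.  The gyrification index is
surface area over convex-hull area; sulcal depth is the distance to the hull
boundary (for interior points of a convex body this is exactly the minimum
facet-plane distance).  Folds are connected components of sulcal vertices
(shape index below -0.25, depth above 2% of the hull-equivalent radius, at
least 10 vertices by default; the desk-scale tests lower the component
minimum to 3-5 vertices because their surfaces carry only 10² — 10³
vertices).  On tightly packed (polymicrogyria-like) surfaces the sulci
percolate into a single connected labyrinth while the gyral crowns become
isolated islands; `count_folds(phase="folds")` therefore reports the larger
of the sulcal and gyral component counts (zero when no sulcal vertex
exists), which stays monotone in the number of folds across both regimes.

Spherical parameterization uses conformalized mean curvature flow (fixed
input cotangent Laplacian, evolving lumped mass matrix), followed by radial
projection and a Moebius normalization placing the area centroid at the
origin.  Landmark alignment uses the closed-form optimal rotation (Kabsch) on
paired landmark directions: rotations are the Moebius transformations that
preserve both the centroid normalization and the discrete per-triangle
conformal distortion exactly, so alignment can never degrade conformality.
Harmonic spectra are area-weighted least-squares projections onto real
spherical harmonics; surfaces are compared by resampling fields on a
Fibonacci grid (mean absolute difference, Pearson correlation) and by
per-degree band energies of the coefficient difference.

## Numerical choices and degenerate inputs

* Indicator overflow: theta is evaluated through the logistic `expit`, exact
  to double precision at both saturation ends.
* Degenerate triangles (area < 1e-12) flag their vertices during curvature
  computation instead of failing.
* Meshes read from files are validated: positive tet volumes (the offending
  element is named), watertight boundary, closed 2-manifold surface.
* The stepwise protocol rebases the material reference onto the relaxed
  state at each stage boundary (re-deriving depth, indicator and growth
  normals there); the reference study restarts each stage from a newly imaged
  brain, which no synthetic pipeline can reproduce — rebasing is the
  documented stand-in.
* Determinism: every stochastic ingredient (surface noise, slab jitter) is a
  pure function of the configuration seed; identical configurations
  reproduce identical meshes and metrics byte for byte.

## Known limitations

* Uniform stiffness: a single `mu` for gray and white matter (the energy has
  one shear modulus); stiffness-contrast experiments would need a small
  extension of the element loop.
* No viscoelasticity, no stress-modulated growth, no anisotropic white
  matter.
* Contact is frictionless and purely repulsive; deeply interlocked folds can
  slide along each other freely.
* The desk-scale fold counts are lower bounds for the thin-cortex scenarios
  (see above); quantitative wavelengths carry ~20-30% mesh bias at these
  resolutions.
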