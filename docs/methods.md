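# Methods

`aneumorph` quantifies the 3D shape of isolated intracranial-aneurysm domes
and benchmarks how well those quantities discriminate rupture status.  This
note documents the models, estimators, parameter choices and known limits.

## Input model

The geometric substrate is a sanitized 2-manifold triangle mesh in
millimetres — either closed (test solids) or with one or more open boundary
loops.  Sanitization merges duplicate vertices at 1e-9 mm, drops degenerate
faces, unifies winding and orients normals outward; edges bounding more
than two faces are a hard error.  A cut dome carries its neck as the
longest open boundary loop (additional loops are treated as artifacts and
logged).  The neck reference plane is the total-least-squares plane through
the cut line, oriented toward the dome; the ostium area S_n is the area of
the contour projected onto that plane, and the characteristic neck diameter
is D_n = 4·S_n/P_n.  For volume, open domes are capped by fan-triangulating
the boundary against the centroid of its planar projection — exact for
star-shaped neck contours; non-star-shaped contours fail loudly rather
than silently mis-capping.

Two dome-type cut conventions are distinguished: *dome* (single planar cut)
and *ninja* (non-planar cut along the anatomical neck line).  Cuts
retaining parent-vessel stubs (*cut1*/*cut2*) are supported only for the
cut-agnostic feature families (curvature, writhe, Zernike).

## Feature families

**Geometry indices** (dome-type cuts only).  Size: volume V, neck-free
surface area S, neck diameter D_n, maximal cross-section diameter D_max,
height H (maximal signed distance to the neck plane) and aneurysm size aSz
(minimum-bounding-sphere diameter, via trimesh with a Welzl fallback for
degenerate point sets).  Shape: AR = H/D_n, BF = D_max/D_n,
CP = 0.5 − H_Dmax/H, NSI = 1 − (18π)^{1/3}·V^{2/3}/S, EI (NSI evaluated on
the convex hull) and UI = 1 − V/V_CH.  NSI and EI are 0 for an ideal
half-sphere; UI is 0 for convex domes.

Choices a user should know:

- Cross-sections for D_max use the same 4·A/P characteristic diameter as
  the neck (keeping BF a pure shape contrast), evaluated on 100 slices
  placed at midpoints of a uniform partition of (0, H].  Ties for the
  widest slice (within 1e-9) resolve to the lowest slice, making CP
  deterministic and maximal.
- The hull surface S_CH used by EI excludes hull facets whose centroids lie
  within 1e-6·aSz of the neck plane, mirroring the neck-free definition of
  S; this makes EI(half-sphere) = 0 consistent with NSI.
- UI values in (−1e-6, 0) arising from shared-vertex rounding between the
  capped dome and its hull are clamped to 0.

**Curvature indices** (any cut).  Per-vertex Gaussian curvature is the
angle deficit over the mixed Voronoi area (with the standard obtuse-
triangle clamp); mean curvature is half the magnitude of the cotangent-
Laplacian mean-curvature normal, signed positive where the surface is
convex.  Boundary vertices are excluded from all aggregation (the angle
deficit is undefined there).  The aggregates are normalized to be
dimensionless and equal to 1 on a sphere of any radius:
GLN = (1/4π)·Σ|K_G|A and MLN = Σ|K_M|A / √(4π·S).  NGLN/NMLN restrict the
sums to vertices of negative curvature (each field uses its own sign).
GLN_CH and MLN_CH divide by the corresponding totals of the convex hull;
for open domes the hull vertices that coincide with the cut boundary are
excluded so a convex dome scores exactly 1.  Users comparing against other
published total-curvature norms should rescale: only the sphere
calibration and scale invariance are fixed here, not any particular
historical normalization.

GH and MH are Shannon entropies (natural log) of the area-weighted
curvature histogram with 30 equal-width bins spanning [min, max] of the
field.  An exactly constant field has entropy 0; note that a *numerically
jittering* near-constant field (e.g. discrete curvature of a tessellated
sphere) spreads across bins and does not score 0 — the estimator measures
the spread of the discrete values, full stop.

**Writhe indices** (any cut).  The per-vertex surface writhe collects
Gauss-integral interactions with every face c outside an exclusion zone:
g(p,c) = [(n̂_p × n̂_c)·(b_c − p)/|b_c − p|³]·A_c, and
W_Lk(p) = (1/4π)·(Σ_c |g|^k)^{1/k} for k = 1, 2, with area-normalized
variants W̄ = W/S.  The exclusion zone is the union of p's one-ring (the
kernel diverges there) and a metric ball of radius 0.05·√S; the metric
component keeps the excluded neighbourhood independent of tessellation,
without which the indices drift linearly with edge length.  Aggregation:
area-weighted mean and histogram entropy (same estimator as curvature) for
each of {L1, L2} × {raw, normalized} — eight indices.

Known properties of this kernel: raw W is dimensionless and scale
invariant while W̄ scales as 1/S; W_L1 ≥ W_L2 pointwise (ℓ1/ℓ2 norm
inequality); on an exactly sphere-symmetric surface the continuum
integrand vanishes, so discrete values there are tessellation noise; and
the ℓ2 variant shrinks with mesh refinement (the ℓ2 norm of a partition of
a fixed signal scales with √(cell size)), so refinement-robust comparisons
should use the L1 indices.  Meshes above 5000 vertices are subsampled to
5000 evaluation points by seeded area-uniform sampling (approximation
knob; deterministic).

**Zernike invariants and energies** (any cut).  The surface is centered on
its area centroid, scaled so the farthest vertex sits at radius 0.7 of the
unit ball, and rasterized into a cubic grid (default 64³).  Occupancy is
exact triangle/voxel intersection (separating-axis test); voxel weights
carry the surface-area measure deposited by a deterministic half-voxel-
pitch barycentric sampling of each triangle.  The area weighting acts as
anti-aliasing and is what keeps the invariants stable under rotation at
moderate grids.  Complex 3D Zernike moments Ω_{n,l}^m are projections onto
R_nl(r)·Y_l^m(θ,φ) with the standard unit-ball-orthonormal radial
polynomials (q-coefficient form, exact integer binomials); the rotation
invariants are F_{n,l} = √(Σ_m |Ω_{n,l}^m|²), 121 values for n ≤ 20.
Normalized energies Z_N = Σ_{n≤N,l} w_{n,l}·F²/fill with unit default
weights and fill = V / ((4/3)π(aSz/2)³); the order set defaults to
{2, 3, 6, 10, 20} and is configurable.

Discretization limits worth knowing: rotation invariance holds to about 1%
of the largest invariant at grid 64 (invariance statements are therefore
made in the descriptor sup-norm — per-component relative error is
meaningless for near-zero high-order invariants); lattice aliasing leaves
high-order invariants of a sphere at ~1.5% of F_{0,0} at grid 64,
dropping below 1% at grid 96.  Volume-based moments are not implemented;
the voxelization object is the natural extension hook.

## Synthetic domes and cohorts

No clinical meshes ship with the package; the generator emulates cut domes
directly.  A dome is a radial graph over the upper half-sphere: a base
half-ellipsoid with half-axes (a, b, c) mm, multiplied by a radial factor
composed of Gaussian blebs (direction, footprint, height) and a random
real-spherical-harmonic undulation pattern (degree 5–6, amplitude up to
0.5 of the local radius).  The *dome* cut boundary lies exactly in a
plane; *ninja* cuts modulate the polar extent of each meridian
sinusoidally.  All randomness flows through seeded PCG64 generators;
identical specs give bit-identical meshes.

Cohorts draw, per case: an anatomical location from the 12-category
empirical frequency table of a multicentric clinical cohort; latent
irregularity and size variables z ~ N(0,1); and a rupture label from
logit p = β₀(location) + β_shape·z_irr + β_size·z_size + ε.  Defaults:
n = 200, β_shape = 1.5, β_size = 0.3, ε ~ N(0, 0.5); β₀ is the logit of
the per-location rupture fraction with a +0.5 pseudo-count (one location
has zero observed ruptures).  The irregularity latent maps monotonically
to elongation (c/a up to 1.9), undulation amplitude and bleb size, so
irregularity-sensitive features (NSI, UI, writhe, energies) are monotone
readouts of it; size is a pure isotropic scale, lognormal with median
2.8 mm (aneurysm sizes ≈ 2–20 mm).  Every case logs its latents and
logistic score, so the attainable discrimination (oracle AUC) is
computable independently of any measured feature.

What the generator does *not* emulate: parent vasculature, imaging/
segmentation noise, operator variability in cut placement, and correlated
multi-aneurysm patients.  Passing benchmarks on synthetic cohorts
demonstrates that the pipeline measures and recovers the signal it is fed
— not that the same effect sizes hold in clinical data.

## Benchmark

Univariate screening uses two-sided pooled-variance t-tests with a
Bonferroni threshold α/d (d defaults to the assembled feature count).
Classification uses L1-regularized logistic regression throughout.  The
morphometric block is standardized with training-derived statistics;
location enters as 12 unstandardized one-hot dummies appended after any
PCA; PCA (optional, per model config) keeps the smallest component count
reaching 90% of training variance.  The regularization strength λ is
selected from a 30-point log grid on [1e-3, 1e2] by an inner stratified
5-fold search maximizing AUC, ties toward stronger regularization.
Internal validation is stratified 5-fold cross-validation with 20 repeats
(100 evaluations), transformers and λ refit on training folds only; the
final model is refit on all data.  Operating points are taken at the ROC
point closest to (0, 1).  External validation freezes model, transformer
and threshold, and reports mean ± SD over 100 bootstrap resamples of the
external cohort (single-class resamples are redrawn; per-bootstrap
threshold re-optimization is available behind a flag).

Named model configurations: MAX (all features except Zernike invariants of
order ≥ 10, with PCA), BUP (features whose training-partition univariate
AUC exceeds 0.7 — the empirical rank AUC, symmetrized, computed inside
each training partition to avoid selection leakage), LOC (location only),
and the +LOC variants, plus the two-predictor NSI+LOC and Zsurf6+LOC.

Cut-configuration sensitivity uses δ′ = median/IQR of per-case feature
differences between two cut types, quartiles by linear interpolation;
IQR = 0 with nonzero median reports ±∞ with a warning, and 0/0 gives 0.
Category summaries average the finite δ′ within feature families.

## Problem sizes and numerical defaults

The test and acceptance workloads use: hemispheres at 48–72 latitude rings
(9k–21k faces) for analytic calibrations; irregular domes at 20–32 rings
for invariance batteries; 300-case cohorts at 12 rings with geometry-only
descriptors for the statistical properties; Zernike grids of 32–96; and
reduced λ grids (6 points) with 4–5 CV repeats where a property does not
depend on grid density.  Geometric tolerances: merge 1e-9 mm; rigid-motion
and scale checks at 1e-6 relative for mesh-derived quantities,
1–2% for discretization-limited estimators (curvature, Zernike).

## Limitations

- All indices inherit mesh-quality sensitivity; only NSI-type integral
  indices and low-order Zernike invariants are demonstrably robust to 2×
  decimation in the shipped tests.
- The writhe kernel is one concrete realization of a surface Gauss
  integral; published surface-writhe variants differ in kernel and
  normalization, so absolute values are not comparable across
  implementations.
- The benchmark measures association with a binary rupture-status label;
  it makes no claim about prospective risk or wall instability.
- Clinical headline effect sizes depend on cohort composition (rupture
  ratio, location mix, size distribution); the external-validation tools
  exist precisely because frozen models transfer poorly across differently
  composed cohorts.
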