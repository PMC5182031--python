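# Methods

This note records the models implemented in the package, the defaults
and why they were chosen, and the numerical decisions that a user of the
results should know about.

## Fixel data model

A fixel is one fibre population of one voxel, characterised by an axial
unit direction (v and −v are the same fixel) and named scalar metrics.
Grids store per-voxel `(count, offset)` indices into flat per-fixel
arrays; on disk this is a directory of NIfTI files (`index`,
`directions`, one volume per metric), NIfTI-1/2 accepted on read and
NIfTI-2 written. 2-D data ride as `(nx, ny, 1)` grids with identity
behaviour along z so every operation has a single code path. Directions
deviating from unit norm by more than 1e-4 are renormalised with a
warning; beyond 1e-2 they are rejected.

## Fibre density (FD)

FODs are real, even-order spherical harmonics (orthonormal basis; m = 0
the real Y_l0, m > 0 the √2-scaled real parts, m < 0 the √2-scaled
imaginary parts — the convention of the common FOD ecosystem, so
constrained-spherical-deconvolution outputs load directly). FD of a
fixel is the integral of its FOD lobe: the FOD amplitude is sampled on a
dense hemisphere (one representative per antipodal vertex pair of a
4-times-subdivided icosphere, 1281 vertices, ≈ 4° spacing), weighted by
spherical-Voronoi cell areas (they sum to 2π over the hemisphere), and
summed per lobe.

Lobes are segmented by steepest-ascent watershed on the mesh graph:
every positive vertex walks to its highest neighbour until a local
maximum; vertices reaching the same maximum form a lobe. Plateaus of
exactly equal amplitude move as a single node (so a constant FOD is one
lobe, not 1281), and ties are broken deterministically toward the lowest
vertex index. A zero-crossing boundary definition would be the natural
alternative; watershed was chosen because it needs no level threshold
and assigns every positive vertex. Negative amplitudes (small negatives
survive spherical deconvolution) are clamped to zero for integration,
so with a zero threshold the lobe integrals sum exactly to the
hemisphere quadrature of the clamped FOD. Peak directions are refined
below mesh resolution by a quadratic fit in the tangent plane over the
peak's one-ring; recovered peaks of synthetic two-fibre crossings land
within 2° of construction.

Defaults: fixel-mask threshold 0.10 on the lobe integral and at most 3
fixels per voxel — both conventional working values for FOD-derived
fixel masks, configurable everywhere they appear.

## Fibre-bundle cross-section (FC)

Warps are *pull-back* deformation fields: each template voxel stores the
corresponding physical (mm) position in subject space. Displacement
fields (offsets) convert to deformations by adding the voxel's own
physical position. Jacobians are finite differences in physical
coordinates through the image affine (anisotropic or rotated grids are
handled), central in the interior, one-sided at boundaries — exact
everywhere for affine warps; singleton axes contribute an identity
column.

For a fixel direction v̂ in the template, FC = det(J)/‖J v̂‖: the volume
change with the stretch along the fibre divided out, i.e. the area
change of the plane perpendicular to the bundle. FC > 1 means the
subject bundle is larger than the template's. The same quantity computed
by the decomposition route — Gram–Schmidt frame with v̂ first, area of
the image of the perpendicular plane projected perpendicular to J v̂ —
is kept in the package purely as an independent oracle; the two agree to
1e-9 on random well-conditioned Jacobians. Fixel directions transform as
v̂′ = J v̂/‖J v̂‖.

det(J) ≤ 0 (a folded warp) is a hard error naming the offending voxels,
never silently clamped: a folded warp yields meaningless FC and would
quietly corrupt group statistics. FC is analysed raw by default; a log
option exists. FDC = FD × FC elementwise.

## Correspondence

Template-mask fixels take the metric value of the angularly closest
subject fixel in the same voxel, using the axial angle
arccos|u·v| ∈ [0°, 90°]. The cutoff is 30°, boundary inclusive;
beyond it the fixel is zero-filled (a missing population *is* zero
density, not missing data). Equidistant candidates resolve toward the
larger metric value (the dominant lobe). One subject fixel may serve
several template fixels; a one-to-one assignment would be the
alternative but is not imposed.

## Phantom validation

The phantom is a straight 2-D bundle (FD = 1, direction x) on a
48 × 48 unit-voxel grid, 8 voxels wide, mid-line at y = 0. Three
pull-back warps are applied: a length scaling `[[2,0],[0,1]]`, a shear
`[[1,0],[0.5,1]]`, and a piecewise-cosine displacement of amplitude
s_x/8 voxels with opposite signs above and below the mid-line, smoothed
with a σ = 5 voxel Gaussian (reflective boundaries) to remove the
mid-line discontinuity. The grid length of 48 matters: the smoothed
±amplitude step has slope ≈ 2·(s_x/8)/(σ√(2π)) at the mid-line, which
exceeds 1 — folding the warp — once s_x goes much beyond 50 at this
amplitude-to-smoothing ratio. At s_x = 48 the minimum Jacobian
determinant is ≈ 0.23. The 48 rows give the sheared bundle's full
cross-section room at every sampled position.

The warped bundle is built by pulling FD through the warp (trilinear,
anti-aliased with 4×4 sub-voxel samples per voxel so partial-volume
edges are represented), reorienting directions through the inverse
Jacobian, and evaluating FC per voxel. Cross-section profiles start at
the bundle mid-line (FD centre of mass of each image column, sampled
where the mid-line FD is within 5% of full — the bundle's end caps,
where the image truncates it, are not cross-sections), then step 0.1
voxel perpendicular to the locally interpolated fixel orientation
(bilinear, sign-aligned step to step) until interpolated FD falls below
0.05·FD0; sums are Riemann sums scaled by the step. Columns whose
traverse leaves the grid early are flagged invalid rather than reported.
Halving the step changes the sums by < 0.5%.

Under all three warps the summed FDC across the width matches the
untransformed summed FD to well under 2% at every sampled position (the
residual is interpolation error); summed FD alone is conserved only
under the pure scaling. FC is exactly 1 under the scaling and exactly
√1.25 under the shear (linear fields make the finite-difference Jacobian
exact).

## Statistics

Fixel-wise OLS GLM; t = c'β̂/SE with pooled residual variance at n − p
degrees of freedom. FWE across fixels is controlled by max-statistic
permutation: the observed |t| per fixel is ranked against the
permutation distribution of max|t| over fixels, p = (b+1)/(m+1) — valid
at any m, floor 1/(m+1). Nuisance covariates use Freedman–Lane: the
nuisance-only model is fitted, its residuals are row-permuted (all n!
permutations enumerated when n! ≤ the requested count), and the full
model is refitted per permutation. The statistic entering the max step
is pluggable via an `enhance` hook; the default is the raw |t| map, and
a connectivity-based enhancement can be supplied there by users who have
a template tractogram — a deliberate design choice, since enhancement
is a separable concern from the measures themselves. Tests are
two-sided by default with sign-split significance masks (a directional
hypothesis, e.g. patients below controls, reads the negative-contrast
mask).

Validity is demonstrated by simulation at desk scale: 200 null
replicates (20 subjects, 200 fixels, 1000 permutations) give empirical
FWE within binomial error of the nominal 0.05 (asserted ≤ 0.08), and a
planted Cohen's d = 3 effect in 10 of 200 fixels is recovered at ≥ 9 of
10 fixels (median over seeds).

## Synthetic cohorts

`make_synthetic_cohort` emulates a matched cohort as multiplicative
perturbations of a template: subject metric = template × group effect ×
lognormal(0, σ) per fixel, deterministic per seed. Defaults (effect
ratio 0.7 where planted, σ = 0.1) correspond to a strong, clearly
detectable group difference with ~10% biological scatter. This emulates
*matched* fixel data only: it does not simulate registration error,
fixel mis-segmentation, missing fixels, or spatially correlated noise —
so passing tests demonstrate the correctness of the statistical
machinery, not robustness of the full pipeline to real-data artefacts.

## Known limitations

- FOD segmentation loops over voxels in Python; whole-brain volumes work
  but are not fast.
- No warp inversion/composition or registration: warps are inputs.
- Streamline tangents use central differences; heavily curved
  streamlines sampled coarsely will misassign near bends.
- The cross-section profiler assumes a single dominant fixel per voxel
  along the traverse (true of the phantom; crossing regions would need
  per-fixel tracing).
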