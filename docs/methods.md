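# Methods

This note documents the models, numerical choices and known limitations
behind `pelvimetry3d`, in the order the pipeline runs.

## Coordinate conventions

All geometry is expressed in the patient **LPS** frame (x = Left,
y = Posterior, z = Superior), millimetres, right-handed. Slicer-style
fiducial files (RAS) are converted on read by negating x and y; the
conversion is an involution and round-trips exactly. Voxel arrays are
indexed `(slice, row, col)`, axial slices along the first axis; array
axes map to physical (z, y, x).

Two measures reference fixed axes: **pelvic tilt** uses the vertical axis
of a supine patient, taken as the anterior–posterior unit vector (0, 1, 0)
— the scanner's gravity direction when the patient lies supine — and the
**pelvic inlet angle β** references the transverse plane (normal
(0, 0, 1)). Consequently every measure is invariant under arbitrary rigid
motion except these two, which are invariant under translations and
rotations about their own reference axis. Both axes are configurable
through `MeasureConfig`.

## Landmark schema

The suite needs 20 named fiducials, 19 required; `SACRAL_PLATFORM_CENTER`
is optional and defaults to the sacral promontory, because at measurement
precision the centre of the S1 endplate and the promontory marker are
interchangeable for the tilt line. Under that identification a reader
placing markers manually needs 18 distinct points.

## The 21-measure registry

Definitions follow the source convention in which the obstetric, true and
diagonal conjugates run from the **superior, middle and inferior** pubic
symphysis to the sacral promontory, in that order. This disagrees with
classical obstetric naming (where the "true" conjugate is the superior
one), but it is the only ordering consistent with reference cohort
magnitudes (obstetric > true); it is fixed, not configurable, and stated
here prominently. Other open points, decided once and documented:

* **Pelvic depth** runs from the midpoint of the *obstetric* conjugate to
  the coccyx tip, and the **inlet/depth ratio** uses the obstetric
  conjugate: with the reference means this reproduces the printed ratios
  for both sexes (126.2/102.8 → 1.2 female, 119.4/111.5 → 1.1 male),
  whereas the true conjugate does not. Configurable.
* **Pubic tubercle height** is read as the symphysis height
  |PS_SUP − PS_INF| (female < male under this reading, anatomically
  plausible); the source never defines it — flagged as an interpretation.
* **Offset angle α** and **inlet angle β** are reconstructions (named but
  never defined in the source): α is the angle at the promontory between
  the true-conjugate line and the upper sacral line (promontory → S3/S4);
  β is the inclination of the obstetric-conjugate line to the transverse
  plane. Both are config-overridable and no accepted result depends on
  their absolute values.
* **Oblique diameter** is taken from the left side by default (sacroiliac
  joint → contralateral iliopubic eminence); side or side-average is
  configurable — whether the original measurements averaged sides is
  unknown.
* Angle measures are reported in degrees (reference tables label every
  row "(mm)"; for angles that is treated as a typesetting slip).

Angles are computed as `arccos` of the clamped normalised dot product
(three-point angles, range [0, 180]) or `arcsin` of the clamped projection
(line-to-plane angles, range [0, 90]); clamping to [−1, 1] absorbs
round-off at collinear configurations.

## Synthetic cohorts

**Template.** Only measure-level summaries of real cohorts are published,
never coordinates, so the template is calibrated by optimisation: 32 free
parameters (7 midline landmarks constrained to the mid-sagittal plane,
6 right-side landmarks free, left side mirrored) minimise the weighted sum
of squared relative errors against the target means, distances at weight
1, angles and ratio at 0.25 (their definitions are partly reconstructed,
so they should bend before distances do). A very weak pull toward the
hand-drawn initial anatomy (relative weight 1e-4) keeps the
under-determined problem well posed; a final unregularised polish step
lets exactly-attainable targets be met to numerical precision, which gives
the calibration its fixed-point property (refitting to measures taken from
an existing landmark set reproduces them to < 1e-6 relative). Distance
residuals above 5% raise an error carrying the full residual report;
obvious geometric impossibilities (triangle-inequality violations along
the sacral chain, a pelvic depth outside what the promontory–coccyx
median permits) are rejected up front with the conflicting measures named.
With the shipped reference targets all distance residuals are below 0.5%.

**Noise.** Each subject is the template plus independent isotropic
Gaussian displacement per landmark. Per-landmark SDs are calibrated so
the realized *distance*-measure SDs approximate the target SDs: the
first-order model Var(m) ≈ Σ_l v_l · ‖∂m/∂x_l‖² (numeric Jacobian) is
solved for v ≥ 0 by NNLS and refined by bounded least squares in
relative-SD space, then a single global factor from a pilot Monte-Carlo
run (300 draws) absorbs the residual nonlinearity. The target SD table is
structurally over-constrained — e.g. the promontory–S3/S4 SD caps the
promontory variance that the obstetric-conjugate SD would like to be
larger — so exact SD matching is impossible by construction; realized
distance SDs land within ~25% of targets, and angle/ratio spreads are
emergent, not fitted. A second pilot run (800 draws) estimates the upward
convexity bias that landmark noise induces in distance means
(E|A−B+ε| > |A−B|) and the template is refit once to bias-corrected
targets, so cohort means of n = 100 land within 3 standard errors of the
targets, measure by measure. No between-measure covariance structure is
targeted: correlations are whatever the landmark noise induces.

**Phantom.** The bone-like solid is a union of capsules (radius 9 mm)
swept along the pelvic rings — inlet ring, pubic symphysis, sacral chain,
and two lateral chains down to the ischial tuberosities — plus 22 mm
femoral-head spheres; every landmark lies on the solid by construction.
Rasterisation (default 2 mm isotropic, ≥ 10-voxel margin, bone 1000 over
background 0, Gaussian noise SD 20 — CT-like contrast and noise) is exact
per voxel centre; an independent quasi-Monte-Carlo quadrature of the same
analytic indicator (`phantom_solid_volume`, scrambled Sobol') serves as
the volume oracle. Spacing coarser than half the capsule radius is
rejected (the shell would thin below two voxels). The phantom reproduces
the one property segmentation needs — bone at the greatest contrast
against background — and nothing else: no cortical/trabecular texture, no
soft tissue, no statistical shape variation beyond the landmark noise.

## Level tracing

Membership: the 4-connected component, containing the seed, of pixels
with |I(p) − I(seed)| ≤ tolerance. Tolerance 0 is the literal
equal-grey-level rule; the default used by the CLI is half the distance
between the two Otsu class means of the slice. The boundary is the
**crack contour**: the closed polygon of pixel-edge segments separating
filled from unfilled pixels, traced with the region kept on a fixed side
(a 5-pixel plus shape yields a 12-edge outline; regions touching the
image border are closed along it). At a corner where two filled pixels
meet diagonally the walk takes the sharpest turn toward the region, so
loops never cross. Processing is strictly slice-wise; per-slice regions
are OR-ed into the 3D mask, and a region covering more than half its
slice is recorded as a provenance warning (seed probably on background),
not an error. Seed suggestion (one seed per supra-threshold component per
slice, intensity-weighted centroid snapped into the component) is a
convenience for automation and testing, not part of the traced algorithm.

## Meshing and the volume audit

Surfaces are extracted by marching cubes at the 0.5 iso-level of the
zero-padded mask, in world millimetres. The enclosed volume is the
divergence-theorem sum of signed origin tetrahedra; it requires a
watertight, consistently oriented mesh (every directed edge appearing
exactly once, with its reverse present) and errors with the offending
edges named otherwise.

Smoothing is the umbrella operator: v ← v + λ·(mean(1-ring) − v). The
pure filter systematically shrinks the surface; at this package's working
resolution (≈ 2 mm edges on ≈ 9 mm-radius tubular bone) λ = 0.3 over 10
iterations removes ≈ 4.6% of the enclosed volume — far outside the 1%
audit this pipeline commits to. The default is therefore the Taubin
two-step (λ = 0.3, μ = −0.32, 10 iteration pairs), which alternates
shrink and inflate passes and realizes ≈ 0.3% volume change on the
phantom fixture; the pure umbrella filter remains available via
`SmoothingParams(method="laplacian")`. "Filter order" maps to the
iteration count; higher-order umbrella neighbourhoods are out of scope.
`check_volume_budget` computes 100·|V_after − V_before|/V_before and the
audit is enforced, not assumed.

## Statistics

Group tables use sample SDs (ddof = 1). The default test is the pooled
Student t from summary statistics (df = n₁+n₂−2), matching the equal
group sizes and the pooled df printed in the reference power computation;
Welch is a flag. Two degenerate conventions: both SDs zero with equal
means gives p = 1; with unequal means it is an error (infinite t). No
multiple-testing correction enters the headline results (matching the
source's 21 uncorrected tests at p < 0.05); Bonferroni and
Benjamini–Hochberg columns are emitted as supplementary output only.
Published per-measure p-values derive from unrounded patient data and are
not exactly reproducible from rounded summaries; verification is by order
of magnitude and threshold agreement.

Power: δ_nc = d·√(n₁n₂/(n₁+n₂)), critical t the central-t quantile at
1 − α/2, power = P(T > t_crit) + P(T < −t_crit) under the noncentral t.
For d = 0.4, n = 100/100, α = 0.05 this reproduces δ = 2.8284271,
t_crit = 1.9720175, df = 198, power = 0.8036475.

The reference cohort's internal accounting is inconsistent (a stated
count of 19/21 significant measures and two named exceptions versus three
printed p-values above 0.05); the package reports whatever the data give
and targets no particular count.

## Problem sizes and determinism

Test and acceptance runs use the sizes the package defaults to: cohorts
of 100 per sex, 2 mm isotropic phantoms (≈ 10⁶ voxels, ≈ 5×10⁴ bone
voxels, ≈ 6×10⁴-face meshes), 300/800-draw calibration pilots, 200-replicate
null simulations at n = 12 per arm, and 2²¹ Sobol' points for the volume
oracle. All stochastic stages take explicit integer seeds and are
bit-reproducible given them.

## Known limitations

* The phantom is a geometric cartoon: capsule-swept cortical shells with
  uniform intensity. Passing tests show the pipeline's algorithmic
  correctness (segmentation ≡ its specification, meshing volumes, measure
  geometry, statistical calibration), not robustness to real CT artefacts,
  partial-volume effects, osteophytes or fixation hardware.
* α and β are reconstructions; their absolute synthetic values should not
  be compared against published angle tables.
* The landmark-noise model is independent and isotropic per landmark;
  real anatomical covariance (e.g. correlated sacrum shape) is absent,
  so multivariate analyses on synthetic cohorts reflect the noise model,
  not biology.
* Segmentation is strictly slice-wise with one intensity window; there is
  no 3D region growing and no model- or learning-based component.
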