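# Methods

## Scope and model

`scnmap` analyses inter-subject covariance of gray-matter (GM) morphology.
Inputs are modulated, spatially normalized GM images (the output of a VBM
segmentation/normalization pipeline — tissue segmentation, registration and
modulation are upstream of this package), a subject table (id, age, gender,
group) and a hippocampus label image on the same grid. Only axis-aligned
grids (diagonal affine) are supported; normalized data live on such grids
and rotated grids are rejected rather than silently resampled.

### Seed definition

The hippocampus label is partitioned at the coronal plane of the uncal apex
(*y* = −21 mm in MNI space) into anterior and posterior seeds. Voxel
membership is decided by voxel-center world coordinates; centers in the
closed band [boundary − gap, boundary + gap] (gap default 2 mm) belong to
neither seed, so the two seeds plus the removed band tile the label exactly
and no center on a band edge leaks into a seed. Left and right hemisphere
labels are treated as separate inputs, giving four seeds in the full
analysis. Seed values are means over the *unsmoothed* modulated images by
default (a `seed_from_smoothed` option extracts from smoothed images
instead); the voxelwise target images are smoothed.

### Smoothing

Isotropic Gaussian smoothing with kernel width given as full width at half
maximum: σ(mm) = FWHM / (2√(2 ln 2)), converted to voxels per axis, so the
kernel is isotropic in millimetres even on anisotropic grids. Default
boundary handling is zero padding, the natural convention for masked brain
images (nearest-edge is available). Internal arithmetic is float64
regardless of on-disk dtype. Interior sums are conserved to < 1e-6
relative error when the support is ≥ 3σ from every boundary, and the
measured impulse-response FWHM on a 1-mm grid is 12 ± 1 mm for the default
12-mm kernel.

### Volume trajectory and dispersion

Seed volume vs. age is fit by OLS on [1, age, age²]; the fit reports R²,
the overall F test with (2, n − 3) df, and per-coefficient t-test p-values
(both inferential routes are reported because the quadratic-dispersion
question can be asked of either; the curvature coefficient's t test is the
targeted one). The dispersion series evaluates, at every integer age *t*
in the observed range, the sample variance (n − 1 denominator) of values
for subjects with age ∈ [t − 2, t + 2], omitting windows with fewer than 3
subjects (variance of fewer points is unstable; configurable). The
variance series is then fit with the same quadratic, unweighted by default
(count-weighting available).

**Known limitation.** Adjacent windows share up to ~80% of their subjects,
so the variance series is strongly autocorrelated and OLS p-values for the
curvature coefficient are anti-conservative under the null: in simulation
the one-sided positive-curvature rate at nominal 0.05 runs near 0.2 rather
than 0.025 (heteroscedasticity-and-autocorrelation-consistent standard
errors reduce this only marginally at these series lengths). A significant
curvature should therefore be read together with the effect size and the
plotted series, not as a calibrated p-value. Detection power for a genuine
U-shaped dispersion of realistic magnitude is essentially 1 at n = 240, so
the test remains informative despite the inflation.

### Voxelwise covariance GLM

Every voxel is fit independently by OLS. The single-group model is
Y ~ β0 + β1·Seed + β2·Gender; the two-group model adds Group and
Group×Seed. The seed regressor is mean-centered (this leaves the β1 and
β4 t statistics unchanged and stabilizes the intercept); the group is 0/1
coded with the second label of the pair as 1, so β4 estimates the coupling
difference (group b − group a); gender is 0/1 with female = 1. Total
intracranial volume is intentionally not a covariate: modulation already
encodes brain-size differences. Analysis is restricted to an implicit GM
mask (voxels with cross-subject mean GM > 0.1, configurable) — the
standard in-brain restriction for VBM. t = c′β̂ / √(σ̂²·c′(X′X)⁻¹c) with
df = n − p; voxels with zero residual variance have no defined t and are
flagged NaN and excluded from max-statistic computation rather than treated
as infinite.

### Family-wise error control

Significance is controlled at the map level by max-statistic permutation
rather than random-field theory: permutation is distribution-free, makes no
smoothness assumptions, and its calibration can be verified exactly by
simulation at desk scale. The nominal level (p < 0.05 FWE by height and
extent) is unchanged; only the correction machinery differs from
random-field implementations.

The permutation scheme is Freedman–Lane-style on the effect column: the
column of interest (seed, or the interaction term) is residualized on all
nuisance columns, its entries are permuted, the permuted vector is
re-residualized, and the contrast t is recomputed against
nuisance-residualized data via the Frisch–Waugh–Lovell identity with the
full model's df. This preserves nuisance structure under the null while
breaking the seed–voxel association, and reduces each permutation to one
matrix product across all voxels.

Per permutation two maxima are recorded: the map-wide max t (height) and
the largest cluster size at the primary cluster-forming threshold
(one-sided p < 0.001 on the t distribution; the conventional primary
threshold, configurable). The observed statistic is included in each null
distribution. The height threshold is the ⌈(1 − α)(n_perm + 1)⌉-th order
statistic of the max-t distribution. Cluster sizes are small integers with
heavy ties, so the extent critical value is instead the smallest size whose
null exceedance probability is ≤ α (identical to the order statistic when
ties are absent; with ties the order statistic would admit clusters that
nearly every null map produces). A voxel survives if it reaches the height
threshold or belongs to a forming-threshold cluster at least as large as
the extent threshold.

Simulated calibration: across 200 independent global-null cohorts (n = 40,
12³ grid, 500 permutations) the empirical height-FWE stays within binomial
noise of the nominal 0.05 (`scripts/acceptance.py` recomputes this).

### Clusters and reporting

Suprathreshold voxels are grouped by 18-connectivity (faces + edges, the
dominant neuroimaging convention; 6 and 26 available). Each cluster record
carries the seed name, contrast direction, peak voxel world coordinates
(the member voxel with maximum t, ties broken by smallest (x, y, z)
lexicographically), extent in voxels, and peak t. Printed tables round
coordinates to integer mm; JSON keeps full precision. Peak-sphere means
(closed ball of 4-mm radius around the peak by voxel-center distance, the
nearest voxel always included) and within-group Pearson correlations
support scatter-style reporting of group differences in covariance.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets, not raw MRI:
three age groups (defaults 18–23, 30–58, 61–89 years; 80 subjects each;
female fractions 0.625/0.625/0.6875), integer ages uniform within each
group's range, and per subject a latent seed volume
s = b0 + b1·t + b2·t² + η with η ~ N(0, SD(t)²). Default trajectory
(3.5, 0.02, −0.0005): a GM-volume-like quantity that rises gently to a
mid-life maximum near age 20–50 and declines thereafter. SD(t) is constant
(η_sd, default 0.1) unless a quadratic SD profile is supplied to plant
U-shaped dispersion. Hippocampus-label voxels carry s itself (plus voxel
noise), so the label ROI mean reproduces the latent value exactly in the
noise-free case; every other voxel is
μ + λ_v(group)·s + γ_v·gender + ε, with background μ = 0.5
(GM-density-like scale, irrelevant to inference), per-group coupling maps
λ_v (zero by default), gender effect γ_v (zero by default) and
ε ~ N(0, 0.05²). A fixed integer seed makes generation bit-reproducible.
The null-cohort variant enforces λ ≡ 0 and γ ≡ 0 by contract, leaving the
seed covariate independent of every non-label voxel.

Deliberate simplifications: uniform ages (only ranges and group means are
typically reported for real cohorts; uniformity exercises the windowed
variance estimator at every age), linear voxel–seed coupling, spatially
white Gaussian noise, and no segmentation or registration artifacts.
Passing the planted-recovery and calibration tests therefore demonstrates
correctness of the estimator and inference machinery under the modelled
data-generating process — not robustness to the spatial autocorrelation,
non-Gaussian intensity distributions, or registration error of real VBM
data.

For the U-shaped-dispersion simulations the SD profile is
SD(t) = 0.25 − 0.008·t + 0.0001·t² (≈ 0.14 at age 18, minimum ≈ 0.09 near
40, ≈ 0.33 at 89 — roughly a 3.5-fold lifespan range), a dispersion shape
of the kind reported for the anterior hippocampus: young and old more
heterogeneous than middle-aged.

## Validation problem sizes

The shipped validation studies are sized for a single CPU: FWE calibration
uses 200 null cohorts of 40 subjects on a 12³ grid with 500 permutations;
planted-effect recovery uses 50 replicates of 80 + 80 subjects on a
16×20×16 grid (5³ planted block, coupling difference 0.8, 500
permutations); dispersion simulations use 100 replicates of 240 subjects.
These sizes give binomial/simulation error small enough for the stated
bounds while keeping the full suite in minutes.

## Numerical conventions

- float64 throughout; images may be stored as float32 on disk.
- Voxel membership everywhere (seeds, spheres, labels) is by voxel-center
  world coordinates; closed boundaries (band and ball include their edge).
- Rank deficiency in any design (constant seed, single-gender cohort,
  collinear columns) raises an explicit error naming the problem rather
  than silently dropping columns; three-group input to the pairwise
  interaction model raises an error directing to pairwise calls.
- Degenerate inputs: empty masks and empty analysis grids are errors;
  an empty seed side after partition is a warning (the mask may genuinely
  lie on one side of the plane); zero-variance correlations return NaN.
- Determinism: every stochastic routine takes an integer seed; permutation
  thresholds, generated cohorts and reports reproduce exactly for a fixed
  seed, and run manifests record all seeds used.
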