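# Methods

## Radiodensity calibration

Ethanol is less radiodense than water, and an ethanol–water mixture's mean
radiodensity falls approximately linearly with ethanol volume fraction. The
working calibration is the two-point affine map

c(HU) = (HU − HU₀) / (HU₁₀₀ − HU₀)

anchored at the 0% and 100% ethanol standards. For vial work the standards
are water and pure ethanol; for tissue the 0% standard is the mean
pre-ablation tissue radiodensity, since parenchyma is slightly more
radiodense than water. Concentrations are carried internally as
dimensionless fractions and only scaled to percent at reporting time, which
removes a whole class of double-scaling bugs. `estimate_concentration`
deliberately does **not** clip to [0, 1]: sub-zero and super-unity estimates
are physically meaningful diagnostics (dense tissue, air) and their
treatment is a volumetrics-stage policy.

Two error components are quantified separately:

- **Non-linearity** (systematic): real intermediate mixtures sit slightly
  above the two-point line in radiodensity. The error is the absolute
  difference between estimated and true concentration at each intermediate
  vial, in percentage points. Absolute value is used because a mean of
  signed errors could cancel a bias that is in fact one-sided.
- **Measurement variance** (random): the mean per-vial radiodensity
  standard deviation, reported in HU and as a percentage of the calibration
  range |HU₀ − HU₁₀₀|. Sample standard deviations use the n−1 denominator
  throughout (vial ROIs are finite samples).

An OLS fit of mean HU on concentration (`fit_linear`) is retained purely as
a linearity diagnostic (its r² drops when intermediates are biased); the
two-point model remains the calibration actually applied to images.

## CT volumetrics

The cytotoxic distribution is the set of evaluated tissue voxels with
estimated concentration ≥ 0.20 (default `lower`), because a 10-minute
exposure to 20% ethanol is cytotoxic at the post-injection imaging time and
the threshold also rejects naturally low-radiodensity tissue features. The
optional `upper = 1.20` cut excludes air-bubble artifacts whose ≈ −1000 HU
maps far above any physical concentration; it is off by default because the
artifact arises from open-surgery in vivo scans, not from ex vivo material
submerged in buffer. Disconnected components all count toward the volume —
poorly localized injectate genuinely fragments — and a 26-connectivity
component count is reported as a fragmentation diagnostic.

Shape is summarized as

aspect ratio = (Σᵢ ‖xᵢ − x̄‖ / N) / (3V/4π)^(1/3),

the *arithmetic mean* distance to the centroid divided by the equal-volume
sphere radius. This is the literal printed formula, not the RMS radius of
gyration of mechanics: a uniform solid ball scores 3R/4 ÷ R = 0.75 (RMS
would give √(3/5) ≈ 0.775). The package follows the literal formula and
exposes `SPHERE_ASPECT_RATIO = 0.75` so users can renormalize to a
sphere-equals-one scale. All centroids and distances are computed on voxel
centers in physical millimetre coordinates, so anisotropic spacing is
handled; volumes are voxel counts × voxel volume in µL (≡ mm³ exactly).

Cumulative volume curves report the tissue volume at or above each
threshold on a grid from 0 to max(1.2, observed max) in 0.01 steps; the
grid top covers the >100% artifact tail. The curve at any grid point equals
the thresholded segmentation volume at that point by construction, and is
non-increasing. Maximum concentration projections take the per-ray maximum
along a grid axis; the banded copy floors values to 20-percentage-point
bands (clipped to [0, 1]) for display. Voxels outside the tissue mask are
NaN ("not evaluated") and never enter volumes, curves or projections.

## Histology quantification

NADH-diaphorase stains viable tissue blue and leaves necrotic tissue
unstained, so necrosis is low-blue area inside tissue. The pipeline order
is fixed and order-sensitive:

1. local-entropy filter (default 9×9 window) on the blue channel;
2. binarize at a user threshold — entropy is normalized by its theoretical
   maximum log₂(window²), so thresholds are comparable across slides and a
   texture-free image yields zero tissue rather than an arbitrary mask;
3. delete components < 15 000 px;
4. erode with a flat disk of radius 15 px (a disk is chosen over a square
   for isotropy; both are available);
5. fill holes — this is the step that keeps weakly textured necrotic cores
   inside the tissue mask;
6. dilate with the same element; extract boundaries and area.

For convex tissue away from borders, steps 4–6 form a morphological opening
and are area-neutral; the fill-holes placement between erosion and dilation
is what the golden-fixture order test pins down. Necrosis segmentation then
binarizes the tissue-masked blue channel (necrotic = below threshold),
removes components < 5000 px, keeps the five largest, and drops user-flagged
regions (vessel lumens caught by the same threshold). Exclusions are given
as region indices in a sidecar file rather than interactive clicks, for
batch reproducibility; the five-largest rule is applied before exclusions.
Thresholds are user-supplied per slide by design — staining intensity
varies — and the unit chain is fixed: px → cm² via (pixel size in µm)², and
necrotic volume in µL = Σ areaᵢ(cm²) · step(mm) · 100.

`compare_to_manual` reports both the mean signed and the mean absolute
paired difference between automated and manual areas, without privileging
either as "the" agreement statistic.

## Synthetic data

The generators define the study conditions for all tests:

- **Vial panel** (`default_vial_specs`): 0/25/50/75/100% ethanol, 20
  replicate vials per level, 2000 voxels per vial, Gaussian noise. Endpoint
  means are −66.5 and −340.3 HU with sds 20.3 and 29.1 HU; intermediate
  levels are biased above the two-point line by 2.0/6.2/14.9 concentration
  points (mean 7.7, sd ≈ 6.6) and given sds 18.0/15.0/21.6 HU so the
  five-level mean sd is 20.8 HU — the observed scale of real vial panels.
- **Injection phantom**: a tissue ellipsoid (60 HU) in buffer (0 HU) with
  ethanol inclusions written as HU₀ + c·(HU₁₀₀ − HU₀) + noise, i.e. exactly
  what the calibration inverts; confounders are −1000 HU air bubbles and
  low-radiodensity pockets between buffer and tissue. Default grid 64³ at
  0.5 mm. Both the analytic ellipsoid volume and the rasterized truth-mask
  volume are recorded; they converge as spacing → 0 (verified at two
  resolutions).
- **Slide series**: sections every 1 mm through a necrotic ellipsoid,
  rendered as an unstained gray core (blue ≈ 140) inside blue-dominant
  viable tissue (blue ≈ 200) with multiplicative speckle so the entropy
  filter has signal, on a flat background. Default 512×512 px at 25 µm so
  the fixed 5000-px minimum-region rule stays small relative to real
  cross-sections, as it is on 10× scans. Per-slide analytic ellipse areas
  π·b(z)·c(z) are recorded.

Noise is i.i.d. Gaussian per voxel with no spatial correlation, and the
slide renderer does not attempt realistic liver texture, stain variation,
or sectioning deformation. Passing tests therefore demonstrate correctness
of the measurement chain, not robustness to real-scanner artifacts
(beam hardening, correlated noise) or real staining variability.

## Pipeline

The orchestration layer runs calibrate → quantify-CT → quantify-histology →
correlate per sample, writing per-sample CSV/JSON reports and a provenance
record (SHA-256 of every input file, all parameters, the seed). Outputs are
byte-identical across reruns of the same config. Group statistics stop at
mean/sd and fold-change of group means (with both group labels in the key);
the group-average necrosis-to-distribution ratio is the mean of per-sample
ratios, not the ratio of group means, which matters because the two differ
under the heavy between-animal variance typical of these volumes.
Inferential statistics (ANOVA/Tukey) are out of scope.

## Numerical choices and limitations

- Empty distributions return volume 0 with NaN aspect ratio and a warning,
  never an exception; a single-voxel distribution has aspect ratio 0.
- Degenerate calibration (equal standards, or an ethanol standard at or
  above the water standard) raises immediately at model construction.
- Problem sizes in tests and the acceptance script — 64³ phantoms, 512²
  slides, 10⁴-voxel vials — are chosen so rasterization error is a few
  percent, well inside the stated recovery tolerances, while the whole
  suite runs in about a minute.
- Image registration between pre- and post-ablation scans, CT physics
  (beam hardening), stain chemistry, and whole-slide pyramidal formats are
  out of scope; volumes are NIfTI-1, slides are TIFF/PNG.
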