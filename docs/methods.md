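# Methods

This note documents the models, parameter choices and numerical
conventions behind `stressphen`, and what the synthetic experiments do and
do not demonstrate.

## Camera rig and geometry

The rig model is four pinhole cameras with radial–tangential (plumb-bob)
distortion, extrinsically referenced to the left IR camera's optical
frame (z along the optical axis, towards the soil). Image coordinates are
0-based `(row, col)`. Undistortion inverts the distortion polynomial by
fixed-point iteration (max 20 iterations, tolerance 1e-10); the
round-trip is exact to better than 1e-8 in normalized coordinates over
the realistic coefficient range.

The snapshot-mosaic camera has a 5×5 per-pixel spectral filter array.
The true band-to-tile-offset map and exact band centers of the physical
sensor are not published, so both are configuration: the default layout
is row-major with bands sorted by wavelength, and the default band
centers are 25 evenly spaced values on 600–875 nm (the rig's short-pass
filter blocks above 875 nm). Indicator computations always select the
band nearest the requested wavelength (670, 686, 803, 857 nm), so a
corrected wavelength table changes no code.

Demosaicking is pure subsampling — band *b*'s pixel *(i,j)* is raw pixel
*(5i+r_b, 5j+c_b)* — and therefore exactly invertible on tile-aligned
frames; no spatial or spectral interpolation is introduced.

## Stereo

Depth comes from SAD block matching on the rectified IR pair: winner-take-
all over the cost volume, an ambiguity test (the best cost must beat the
best cost outside ±1 disparity by a ratio of 0.95 — constant images are
fully rejected), equiangular (V-shape) sub-pixel interpolation (less
pixel-locking than the parabola for SAD costs), left–right consistency
at 0.5 px, and a 3×3 validity-masked median filter. Defaults: block 7,
disparity search range `f·b / 0.5 m`.

With the synthetic rig (f·b = 21 m·px at the study scale) one disparity
step is ~4.8 cm of depth at 1 m, so sub-pixel quality matters: on
synthetic frames the median depth error is 1–2 mm and ≥ 90 % of textured
box pixels match the true disparity within 1 px at open-to-mid canopy.
*Limitation*: at full canopy closure the silhouette bands of tall plants
have steep disparity gradients that violate the fronto-parallel window
assumption; accuracy there degrades to the 1–3 px range and the
left-right check discards many silhouette pixels. This is inherent to
local window matching and is why the per-pixel share within 1 px is
verified at mid growth.

## Radiometric normalization

The per-channel reflectance factor is the **mean of per-pixel ratios**
`mean(R / I)` over the panel region (the printed form of the estimator),
not the ratio of means; the two differ under non-uniform panel intensity.
Zero-intensity pixels are excluded. Occlusion is detected in RGB only
(any panel pixel with channel-mean brightness < 0.4); the HS and IR
frames of an RGB-occluded date share the physical scene and are treated
as occluded too. Occluded factors are filled with the mean of the nearest
earlier and later measured factors — factors, not images, are averaged —
with single-sided fallback at the series ends and the reference box as
the last resort. IR factors are computed and stored for completeness but
feed no downstream indicator.

Note that a sufficiently dark illumination gain (panel intensity
`0.6·gain < 0.4`) legitimately triggers the occlusion flag; the
generator's gain range (0.85–1.25) stays clear of it.

## ROI detection

"Gray" is operationalized as max pairwise channel difference ≤ 0.08 with
channel-mean brightness in [0.2, 0.8], intersected with pixels whose
Sobel gradient magnitude exceeds the image's 90th percentile. Both
thresholds are config-exposed; they were chosen on synthetic fixtures.

Method selection: the edge-density fit (each side at the smoothed 1D
histogram peak of point rows/cols within its image half) needs many rim
points and is used when ≥ 200 edge points survive; otherwise the
maximum-empty-rectangle procedure runs. The empty-rectangle search is
exact on the discrete pixel grid (largest all-clear rectangle via the
histogram-stack scan, O(H·W)); ties break to the lexicographically
smallest `(top, left, bottom, right)`. The edge-density fit returns the
detected rim coordinates as an inclusive rectangle converted to half-open
bounds (+1 on bottom/right).

ROI transfer to the point cloud is geometric: points are re-projected
into the RGB camera and tested against the detected rectangle.

## Soil reference and segmentation

Height requires a soil reference, but the height criterion is part of
segmentation — the circularity is broken by a bootstrap pass: the two
reflectance criteria alone mark provisional vegetation, the median z of
the remaining points is the soil depth, and heights are `z_soil − z`
(negative values ignored, recorded as absent). With fewer than 10
provisional soil points the 95th depth percentile substitutes.

Final vegetation flags are the exact union of the three criteria
(excess green ≥ 0.08 on reflectance-normalized color, red-edge contrast
≥ 0.35 with the bands nearest 857/686 nm, height ≥ 0.02 m). Raising any
threshold can only shrink the vegetation set.

## Indicators and statistics

Indices are computed per point and then summarized (not on mean
reflectances); zero-denominator ratios yield absent values. Variance is
the sample variance (n−1) for stability, with single-point sets reported
as 0. Canopy cover and the volumetric estimate use all ROI points and are
independent of the statistic; every other statistic runs over
vegetation-flagged points only. The classifier-facing vector is the fixed
54-column order: CanCov mean, VolEst mean, Height mean+variance, then the
25 band (mean, variance) pairs.

## Classification protocol

Features are standardized per column on training rows only; absent values
are imputed with the training mean (scaled 0); days-after-sowing is
appended unscaled as the 55th component. Within cross-validation the
scaler is re-fitted on each fold's training part so standardization never
sees validation rows.

Because the raw DAS component (range 0–70) would dominate any kernel or
distance computation over 54 standardized components, the SVM and
nearest-neighbor backends re-standardize their inputs internally — the
behavior of the statistics-toolbox presets the original workflow used.
The reference model is an SVM with quadratic polynomial kernel
(`C=1, coef0=1, gamma='scale'`); seven further backends (trees, LDA,
k-NN, bagged trees, random-subspace LDA/k-NN, boosted trees) are mapped
to standard scikit-learn estimators behind a fit/predict registry with
library defaults.

Cross-validation is stratified 5-fold over observations (box-dates), ties
broken by a seeded shuffle; test independence comes from holding out
round(20 %) of whole boxes before any fitting. The sowing-date rows are
dropped (no germinated plants). The ordinal cost matrix applies to the
three-level nitrogen and weed factors; the binary water factor uses the
uniform 0/1 matrix. Costs are used for evaluation; training is not
cost-sensitive (the backends' own class weighting can be added through
the registry).

The water label is "Sufficient" for every box through day 28 inclusive
and "Drying" for water-limited boxes afterwards.

## Synthetic study design

The generator emulates the experiment's statistical structure rather than
its photometric detail. One box is 40×20 cm at 1 m depth; six beet plants
are paraboloid height fields on a 2×3 grid with seeded positional and
size jitter; weeds are small clumps (≤ 0.05 m tall). Growth is logistic
in days after sowing (cover rate 0.15/day, midpoint day 30, asymptote
55 % cover; height rate 0.12/day, midpoint day 32, asymptote 0.22 m;
germination at day 4 with a 1.2 cm seedling floor).

Stress effects (the study conditions; all config-exposed):

* **Drought** — water-limited boxes halve the height growth rate after
  day 28 (irrigation stop).
* **Nitrogen** — the vegetation NIR plateau (0.50 unstressed) is
  depressed by 0.18 / 0.09 / 0 for low / medium / high supply, and growth
  is stunted by the factor 0.7 at low supply (medium supply is already
  sufficient, mirroring the reference measurements).
* **Weeds** — 2–4 (medium) or 7–12 (high) clumps per box with a slightly
  distinct spectrum (higher red base, lower NIR plateau); weeds share
  80 % of the box's nitrogen NIR depression, as weeds growing in the same
  substrate do.

Rendering is exact pinhole ray–paraboloid intersection, so the stereo
pair and the true disparity map are geometrically consistent by
construction. Reflectance is modulated by seeded two-octave value noise
anchored in world coordinates (hence stereo-consistent), scaled by a
per-frame illumination gain (uniform 0.85–1.25) and perturbed by additive
Gaussian sensor noise (σ = 0.01). Brightness and a small size wobble are
redrawn per measurement date: day-to-day variability is realistic, and
without it the observation-level cross-validation can memorize per-box
fingerprints (which would lift even zero-effect accuracy above chance).

Ground-truth box traits are computed from the scene parameters on a fine
soil-plane grid, never from renders. Cover is the covered-area fraction;
mean height and mean band reflectances are weighted by the projected
solid angle (1/z² of the canopy surface) because that is the quantity a
per-point mean over an ideal point cloud estimates. Point-level
segmentation truth uses the RGB-camera material mask (the finest
available) with the same nearest-pixel projection as the fusion step.

The synthetic rig's band images have the same resolution as the IR pair
(mosaic 1600×1200 at full scale). At much coarser band sizes the 5×5
spatial–spectral aliasing of the mosaic creates false red-edge responses
along every material boundary; with real plant-to-pixel ratios this is
negligible, but at desk scale it would dominate, so the rig compensates
with resolution.

**What the studies show, and what they do not.** Passing the recovery
study shows the *pipeline* preserves the treatment signal end-to-end —
through demosaicking, normalization, stereo, fusion, ROI, segmentation
and feature extraction — well enough for the stated classifier to recover
severity labels, and that with zero effect sizes it recovers nothing
(accuracy within ±0.1 of the best constant predictor, which is the
appropriate chance level under the plan's unbalanced class priors). The
synthetic canopies have none of the photometric complexity of real
plants (specularity, shadows, leaf-angle BRDF effects, senescence), so
absolute accuracies do not transfer to real imagery.

## Numerical / reproducibility conventions

* All randomness flows from integer seeds; scene layout depends on
  (seed, box), per-date variation on (seed, box, day). Identical seeds
  give byte-identical trait CSVs.
* Trait CSVs print 9 significant digits with deterministic (box, date)
  row order; absent values are empty cells.
* Images on disk: 16-bit PNG for mono intensities (10000 DN per unit),
  8-bit PNG for RGB (127.5 DN per unit; the imaging backend cannot write
  16-bit RGB PNG), float32 TIFF for HS mosaics. Point clouds are binary
  little-endian PLY with x/y/z, uchar RGB, 25 float band properties and a
  uchar vegetation flag.
* The default studies run at half image scale (RGB 320×240, IR 160×120,
  HS mosaic 800×600); full scale is a config flag.

## Known limitations

* Local block matching underestimates heights by a few millimeters at
  mid growth (the whole canopy spans < 2 px of disparity there) and
  degrades on steep silhouette bands at canopy closure.
* The maximum-empty-rectangle ROI procedure is exact but brittle to any
  stray "gray" detection inside the box, as expected; the density fit is
  preferred whenever enough rim points survive.
* With a near-saturated single-modality signal (nitrogen via HS), the
  full multimodal feature set occasionally trades one cross-validation
  row against the HS-only subset — ceiling effects make the ablation
  margin zero rather than positive there.
* Occlusion handling is temporal only; no spatial inpainting of the
  panel is attempted.
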