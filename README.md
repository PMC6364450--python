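# stressphen

Spatio-temporal-spectral plant stress phenotyping from box-scale
greenhouse imagery.

Sugar-beet cultivation boxes are imaged from ~1 m above the soil on
biweekly measurement dates with three sensors: an RGB camera, a rectified
infrared stereo pair and a 5×5 snapshot-mosaic hyperspectral camera
(25 narrow bands, 600–950 nm). `stressphen` turns each box-date's four raw
images into a **spectral 3D point cloud** — every point carries Cartesian
coordinates, RGB color reflectance and 25 narrow-band reflectances — and
from it derives plant trait indicators that feed cost-sensitive
classifiers for the severity of three simultaneously occurring stresses:
**drought, nitrogen deficiency and weed pressure**.

The pipeline, per box-date:

1. **Demosaicking** — the snapshot mosaic is split into 25 band images by
   pure subsampling (band *b* pixel *(i,j)* = raw pixel *(5i+r_b, 5j+c_b)*;
   no interpolation).
2. **Reflectance normalization** — an in-frame panel of known reflectance
   *R* = 0.6 gives per-channel factors
   `f_c = mean over panel pixels of (R / I_pixel,c)`;
   reflectance = `f_c · intensity`. Frames whose panel contains any pixel
   darker than 0.4 are flagged occluded and their factors are filled in
   from the temporally nearest clean frames of the same box (reference-box
   fallback in the worst case).
3. **Stereo → spectral cloud** — SAD block matching with left–right
   consistency produces a disparity map; `z = f·b/d` triangulation gives
   3D points, which are projected into the RGB and hyperspectral cameras
   to pick up color and band reflectances (nearest pixel, no
   interpolation).
4. **Box ROI** — the gray box rim is detected as gray, mid-brightness,
   high-gradient pixels; the rectangle is fitted either at the 1D density
   peaks of the edge points (open canopy) or as the maximum empty
   rectangle containing no edge point (closed canopy). A CSV override
   file replaces interactive correction.
5. **Vegetation segmentation** — a point is vegetation if **any** of
   `2G − R − B ≥ 0.08` (excess green), `R_857nm − R_686nm ≥ 0.35`
   (red edge) or `height ≥ 0.02 m` holds.
6. **Trait indicators** — canopy cover (% vegetation points), volumetric
   estimate (Σ heights), height, per-band reflectance and vegetation
   indices (NDVI = (NIR−R)/(NIR+R) with the 803/670 nm bands, EGI, NEGI,
   NDRI, ERI, band differences), summarized by mean/variance/min/max over
   vegetation points.
7. **Classification** — 55-dimensional feature vectors (54 standardized
   indicator-statistic values + days after sowing), stratified 5-fold
   cross-validation on the training rows, whole boxes (20 %) held out as
   an independent test set, separate models per stress factor, and an
   ordinal misclassification cost
   `cost = (1/N) Σ_ij CM_ij · w_ij` with weights
   `[[0,1,2],[1,0,1],[2,1,0]]` for the three-level factors.

Because the original image corpus is an external download, the package
ships a first-class **synthetic scene generator** (`stressphen.synthscene`)
that emulates the experiment: the 30-box treatment plan (plus a reference
box) over 16 dates, plants as textured paraboloid height fields with
logistic growth, drought halving height growth after day 28, nitrogen
deficit depressing the NIR plateau and stunting growth, 2–4 / 7–12 weed
clumps per pressure level, a constant-reflectance panel in every frame,
per-frame illumination gain and sensor noise — with exact per-pixel
ground truth (material masks, true disparity, true box traits).

## Worked example

Generate a tiny synthetic dataset (2 boxes × 3 dates) and extract traits:

```bash
$ stressphen --seed 1 synth --out demo/data --boxes 2 --dates 3 --scale 0.5
wrote 24 image entries to demo/data
$ stressphen --seed 1 traits --data demo/data --out demo/results
demo/results/trait_table.csv
```

The trait table has one row per box-date with the 54 classifier-facing
columns plus extended indicators:

```
box_id  das  CanCov_mean  Height_mean  HS20_mean  NDVI_mean
 box01    0     0.070751     0.015114   0.358902   0.021710
 box01   35    24.210526     0.034280   0.306461   0.672300
 box01   70    35.864719     0.060219   0.316377   0.654873
 box02    0     0.000000          NaN        NaN        NaN
 box02   35    24.616267     0.033762   0.320595   0.671646
 box02   70    35.464744     0.062920   0.321843   0.645931
```

Reading it: on the sowing date the boxes are bare soil (cover ≈ 0, no
vegetation statistics); by day 35 the canopy covers ~24 % of the box at a
mean height of ~3.4 cm, and the vegetation NDVI has jumped from soil-level
(~0) to ~0.67, the red-edge signature of healthy leaves. Box01 is a low-N
treatment: its band-20 (~818 nm) reflectance of ~0.31 sits below the
unstressed NIR plateau of 0.5 — the depression the nitrogen classifier
exploits.

On a full-size study, `stressphen classify --traits … --labels …` prints
per-factor cross-validation and held-out-box test accuracies plus the mean
misclassification cost, and `stressphen ablate` compares feature subsets
(RGB-only / RGB+3D / HS-only / all / all+time).

## Layout

| module | contents |
| --- | --- |
| `stressphen.optics` | camera model, demosaicking, stereo, triangulation, fusion, PLY I/O |
| `stressphen.radiometry` | panel factors, occlusion detection, temporal fill-in |
| `stressphen.roi` | gray-edge detection, edge-density fit, maximum empty rectangle, overrides |
| `stressphen.traits` | segmentation, soil referencing, indicators, statistics |
| `stressphen.stress_clf` | labels, feature assembly, CV harness, costs, ablation |
| `stressphen.synthscene` | treatment plan, growth & effect model, renderer, ground truth |
| `stressphen.io_cli` | formats, config, manifests, end-to-end pipeline |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
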