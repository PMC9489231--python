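# Methods

This note records the models, parameter choices and numerical conventions
behind `phenofuse`, and what the synthetic experiments can and cannot show.

## 1. Study design emulated by the generator

The default `SceneConfig` encodes a maize breeding trial: 55 sampled plots
(5 × 11 grid) of 1.2 m × 2.5 m, separated by 0.4 m alleys, observed at 27,
37, 56 and 87 days after sowing (DAS) — 220 plot × stage samples. Imagery
is born orthorectified at 1 cm ground sampling distance (GSD) for RGB and
the height surfaces and 3 cm for multispectral; the two grids must nest
(GSD ratio an integer) so the coarse bands are exact block means of the
fine grid.

### 1.1 Trait model

Each plot *p* carries a latent logistic growth state

  g(p, s) = 1 / (1 + exp(−rate_p (DAS_s − mid_p)))

with rate_p ~ N(0.13, 0.02²) day⁻¹ and mid_p ~ N(40, 4²) DAS. Traits
follow

* LAI = Lmax_p · g, with Lmax_p lognormal (mean 4.65, CV 0.25);
* PH  = Hmax_p · g, Hmax_p lognormal (mean 2.05 m, CV 0.12);
* coverage = 1 − exp(−k·LAI), a Beer–Lambert gap-fraction link with
  extinction coefficient k = 0.7 (typical for maize canopies);
* FW = a·LAI^b (a = 460 g/m², b = 1.6), an allometric biomass–leaf-area
  relation;
* DW = FW · dmf(s) with stage-wise dry-matter fractions
  (0.10, 0.13, 0.20, 0.28) — dry matter accumulates relative to fresh
  weight as the crop matures.

Multiplicative measurement noise (SD 3–8 %) is applied per trait; LAI and
PH trajectories are then made non-decreasing within a plot (cumulative
maximum), since true leaf area and height do not shrink over this window.
DW ≤ FW holds by construction (dmf < 1).

These parameters were set once so the pooled 220-sample statistics land in
the range a real breeding campaign shows — means near LAI 3.1, PH 1.26 m,
FW 3.4 kg/m², DW 0.76 kg/m², with every coefficient of variation above
50 % — and are not tuned per experiment.

### 1.2 Sensor forward model

Canopies are unions of per-plant discs on a jittered 3-row sowing grid
(plant centres fixed across stages and snapped to fine-grid pixel centres).
A single radius threshold per plot × stage is chosen by order statistics of
the distance field so that the rendered maize-pixel fraction inside the
analysis polygon equals the Beer–Lambert coverage to within one pixel —
the rendered label raster is therefore its own coverage oracle. Crowns have
hemispheric profiles h = PH·√(1 − (d/r)²), so the DSM reaches exactly
PH at each plant apex and the 99th CHM percentile sits ≈ 0.5 % below PH.

Reflectance: leaves get nir ≈ 0.40 + 0.02·LAI (capped 0.60), red ≈
0.075 − 0.003·LAI, red-edge ≈ 0.28 + 0.012·LAI; soil is fixed
(0.16/0.20/0.23/0.26 for g/r/re/nir). The multispectral bands are exact
3 × 3 block means of the fine-grid leaf/soil map, i.e. a linear spectral
mixture, which reproduces the concave, saturating reflectance-vs-LAI
response of closing canopies (the mean plot nir has non-positive second
differences in LAI; the generator's slight leaf brightening with LAI keeps
the curve strictly increasing so dense canopies remain distinguishable).
RGB digital numbers use class colours (leaf colour drifts with growth
stage, emulating senescence; within-canopy brightness follows the crown
profile, which is what gives plots their texture signal), cast shadows are
the canopy mask shifted 0.1 m and darkened, and sparse bright debris
("other") is scattered on soil so the 4-class classifier is genuinely
exercised. Sensor noise defaults: reflectance SD 0.01, DN SD 6, DSM SD
0.02 m. DSM never dips below the DEM on maize pixels (crown height + noise
is floored at ground).

What the generator does **not** emulate: photogrammetric artefacts
(stitching seams, GCP error), radiometric calibration drift, mixed
soil/leaf RGB pixels at crown edges, bidirectional reflectance effects,
weeds, or lodging. Passing tests therefore demonstrate the pipeline's
internal correctness and its statistical behaviour under a clean forward
model, not field-level accuracy.

## 2. Geometry conventions

World coordinates are metres in one projected frame. The affine
geotransform maps edge-based pixel coordinates (GDAL convention); pixel
(row, col) has its centre at transform·(col + 0.5, row + 0.5). A pixel
belongs to a plot iff its centre lies **strictly inside** the plot polygon
— one shared rule for coverage, spectral, texture and height extraction
(centres exactly on the boundary are excluded). Analysis polygons shrink
the sown rectangle by a 0.1 m buffer to avoid mixed border pixels. Nodata
propagates as missing pixels, never as zeros. No reprojection is
performed; inputs must share a coordinate frame.

## 3. Feature extraction choices

* **Pixel classifier:** RBF-kernel SVM, C = 10, standardized features
  (R, G, B + chromatic coordinates R/(R+G+B) …), one-vs-one multiclass.
  The kernel and C are conventional choices for colour-space separation;
  the classifier family matters more than the exact settings on
  well-separated classes.
* **Plant height statistic:** 99th percentile (linear interpolation) of
  the truncated CHM over maize pixels — robust to DSM spikes while close
  to the true apex height; the percentile is a config knob. Negative CHM
  is truncated to 0 (sub-ground DSM noise is physically meaningless).
* **GLCM:** 32 gray levels (uniform binning of [0, 255]), distance 1,
  four angles (0/45/90/135°) accumulated into one symmetric matrix
  normalized to sum 1, 7×7 windows slid at step 2 across the plot bounding
  box, keeping windows whose centre is a classified maize pixel inside the
  polygon (a config switch admits all-plot windows). Metric formulas use
  0-based level indices; correlation is defined as 0 when a marginal SD is
  0. 32 levels / distance 1 / 4 angles are the common Haralick defaults.
  Plots with no valid window yield NaN (imputed downstream).
* **Index-of-means:** band values are averaged over the plot's maize
  pixels first and each vegetation index is evaluated on the means
  (per-pixel mode available). RGB indices consume raw DN means on
  [0, 255]; no chromatic normalization.
* **Division by zero** in any index produces NaN, imputed later from
  training-partition medians — infinities never reach the regressors, and
  imputation never sees validation data.
* The multispectral "TO" index is implemented exactly as printed in its
  source table, including its OSAVI denominator and a parenthesization
  that differs from MCARI; its resemblance to TCARI/OSAVI is noted, not
  corrected.

## 4. Regression stack

Base learners (inputs imputed + standardized by a `Preprocessor` fitted on
training rows only):

| model | settings | rationale |
|---|---|---|
| RR | ridge with generalized CV over α ∈ {0.01, 0.1, 1, 10, 100} | spans 4 decades of shrinkage |
| SVM | RBF SVR, C = 10, ε = 0.1 on standardized y | conventional mid-regularization |
| RF | 500 trees, max_features = p/3 | the classic regression-forest default (Breiman); p/3 subsampling decorrelates trees |
| GPR | RBF × constant + white kernel, marginal-likelihood optimization, normalized y | gives calibrated predictive SDs |
| KNN | k = 5, distance-weighted | standard local baseline |

All are overridable per call. The 5-fold split is quantile-stratified on y
(sorted blocks of k, fold labels permuted within blocks) to stabilize
small-n folds.

**Stacking** solves the meta OLS via pseudoinverse so perfectly collinear
base predictions (common when all learners are accurate) stay finite.

**BMA** is fitted by EM on the OOF matrix: responsibilities z_im ∝
wₘ φ(y_i; f_im, σₘ²); M-step wₘ = mean z, σₘ² = responsibility-weighted
residual variance floored at σ_floor = 10⁻⁶ (an exact predictor would
otherwise drive σ → 0 and overflow the likelihood). Initialisation:
uniform weights, σₘ = SD(y − fₘ); stop when the log-likelihood gain drops
below 10⁻⁶ (the trace is non-decreasing, the standard EM guarantee).
Fitting BMA on OOF rather than in-sample predictions keeps it on the same
anti-leakage footing as stacking. At test time both meta-learners consume
predictions of the base models refit on the full training partition.

## 5. Evaluation protocol

75/25 random holdout repeated (default 100×; the heavier test scenarios
use 20× with identical machinery), fresh preprocessing and cross-fitting
inside every training partition, metrics on the held-out quarter, means
(± SD) over repeats. R² is 1 − SSres/SStot on the validation set — not a
squared Pearson correlation; the two differ when predictions are biased.
An optional stage-stratified split is provided; the default is fully
random. Correlation screening uses pairwise-complete Pearson r with NaN
for zero-variance or under-sampled pairs. Trait maps use quantile classes
(default 5) delimited by empirical quantiles; exactly equal predictions
always share a class, so a constant predictor yields one class.

## 6. Problem sizes in the test-suite experiments

The packaged experiments run at sizes chosen to exercise every code path
at desk scale: unit and property tests use 1–16-plot scenes; the
field-scale checks use an 8 × 8-plot, 4-stage scene (256 samples) for
structure recovery (default noise) and for the end-to-end recovery run
(low sensor noise, 20 holdout repeats); the fusion property (49-variable
set ≥ each single-type set) is checked on a 16-plot scene over 20 repeats.
A ±0.02 R² slack is allowed on that comparison because it is a
statistical, not per-run, ordering; near-saturated R² values make tiny
inversions possible.

## 7. Known limitations

* The synthetic forward model is deliberately low-dimensional; absolute
  R²/RMSE on synthetic scenes are optimistic relative to field data
  (coverage and nir carry the LAI signal with little distortion).
* GLCM angles are restricted to the four axis/diagonal directions.
* Only GeoTIFF/GeoJSON/CSV I/O is supported (no Shapefile, no
  reprojection between coordinate systems).
* The GPR predictive SD is the only per-sample uncertainty surfaced; the
  BMA mixture variance is available from its σₘ but not currently exposed
  per prediction.
* Stage-wise trait parameterization is calibrated to pooled dispersion
  targets only; no per-stage field statistics were available to pin the
  stage marginals individually.
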