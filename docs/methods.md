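# Methods

This note documents the statistical model, the synthetic-data generator,
and the numerical and design choices in `cropmapeval`.

## Design-based accuracy estimation

The evaluation treats each candidate map as fixed and the reference sample
as the random object. Reference points come from a probability design —
simple uniform random sampling over the region polygon, or stratified
random sampling with equal allocation over intervals of a covariate raster
(e.g. mean annual NDVI, used where cropland is too rare for a uniform
sample to capture it). Because the sample is a probability sample, the
confusion-matrix cell proportions within each *map* class estimate the
corresponding population proportions, and re-weighting rows by the mapped
area shares `W_i` produces the population error matrix

    p_ij = W_i · C_ij / C_i•

whose entries are estimated proportions of total map area. All metrics
(OA, user's and producer's accuracy, F1) are computed from this matrix, so
they describe the map over its full extent, not over the sample.

**Row-sum normalisation.** The error-matrix denominator is the row sum
`C_i•`. This is the only normalisation under which the matrix rows sum
exactly to the area weights (`p_i• = W_i`) and under which the variance
estimators below (which condition on the per-map-class sample sizes) are
consistent with the point estimates. A column-sum variant is not offered.

**Variance estimators.** With strata identified with map classes:

    V(OA)  = Σ_i W_i² P_i (1−P_i) / (C_i• − 1)
    V(P_i) = W_i² P_i (1−P_i) / (C_i• − 1)
    V(R_j) = [ A_j²(1−R_j)² P_j(1−P_j)/(C_j•−1)
               + R_j² Σ_{i≠j} A_i² (C_ij/C_i•)(1−C_ij/C_i•)/(C_i•−1) ] / N̂_•j²

with `N̂_•j = Σ_i (A_i/C_i•) C_ij` the estimated pixel total of reference
class *j*. Reported uncertainty is the standard error `σ = √V`. The `W_i²`
factor in `V(P_i)` is kept as the package's default (`variance_mode=
"as-printed"`); the more common unweighted within-stratum form
`P_i(1−P_i)/(C_i•−1)` is available as `variance_mode="standard"`, because
the weighted form shrinks the UA error for rare classes and users may
prefer the conservative convention.

**F1 error propagation.** Writing `F1 = X/Y` with `X = 2PR`, `Y = P+R`,
the errors of X and Y derive from the same inputs and are treated as fully
dependent, so relative errors add rather than combine in quadrature:

    ΔF1 = 2(RΔP + PΔR)/(P+R) + 2PR(ΔP + ΔR)/(P+R)²

**Degenerate cases.** If a class is never mapped (`W_i = 0`) its row of
the population matrix is zero and its UA is reported as 0 ± 0; a reference
class with zero estimated area gets PA 0 ± 0; `P + R = 0` gives F1 0 ± 0.
These conventions keep an all-non-crop map's row readable (high OA, zeros
elsewhere) instead of raising on a legitimate, if useless, map. A mapped
class with *no* sample points is an error — nothing can be estimated for
it. A map class with a single sample point has undefined variance; the SE
is reported as 0 with a logged warning.

**Monte-Carlo validity.** Under stratified-by-map-class sampling with
replacement, the analytic SE of OA matches the empirical SD over 2,000
replicates within 10 % relative error (checked in the test suite on a
200×200 synthetic landscape with 150 points per stratum; sampling with
replacement matches the estimator's no-finite-population-correction form).

## Harmonisation

Products arrive as categorical class rasters, probability/score layers, or
crop-area-fraction layers; a `CropClassRule` maps each to binary crop.
Conventions: probability thresholds are strict (`> 0.5` means exactly 0.5
is non-crop); fraction ranges are inclusive on both ends (`5–95 %`
includes 5 and 95); per-date classification stacks are composited by
per-pixel temporal mode before binarisation, with ties resolved to the
lowest class code (deterministic and order-independent).

Resampling to the common grid is nearest-neighbour by cell-center lookup —
values are categorical, so any averaging scheme would manufacture classes.
Cells are half-open (`[left, right)` in x, closed at the bottom edge in y)
so every point falls in exactly one cell. Clipping sets pixels whose
centers fall outside the region polygon to nodata; centers exactly on the
edge count as inside (a measure-zero set needing only a deterministic
rule). Nodata pixels are excluded from every count and statistic, and a
pixel is excluded from consensus analytics if *any* constituent map is
nodata there, since vote counts would otherwise be incomparable.

## Consensus and ensemble

The consensus raster counts crop votes per pixel (0..K). Summary
percentages: unanimous crop (`votes = K`), unanimous non-crop (`votes =
0`), their sum ("all predict same class"), and the split fraction — the
two central vote counts `{⌊K/2⌋, ⌈K/2⌉}` excluding the unanimous ones
(for K = 11 this is 5 or 6 votes; for even K it is the single exact-tie
count). The majority-vote ensemble assigns crop iff strictly more than
half the maps vote crop, so an even-K exact tie is non-crop.

Pairwise agreement is the fraction of jointly valid pixels on which two
maps agree; the matrix is symmetric with the diagonal set to 0 by display
convention, maps ordered by native resolution fine to coarse (ties by
name). Row ranks (1 = lowest agreement) break ties toward the lower
column index via a stable sort.

## Correlates

Per-region metric means across maps use the sample SD (divisor n − 1),
appropriate for the small number of maps. Correlations of per-map mean
metrics against native resolution or temporal mismatch (absolute
year difference) are Pearson product-moment coefficients, reported as *r*
(they are signed; squaring would discard the direction of the relation).
Zero variance in either vector yields NaN, flagged, never a silent 0.
Named maps can be excluded before correlating (the coarse-resolution or
dated outlier analyses); at least three maps must remain. Zonal NDVI
series are per-timestep means over mask-selected pixels, with the mask
resampled to the NDVI grid first — mirroring how crop masks are coarsened
to a 500 m vegetation-index product in monitoring systems.

## Synthetic generator

The generator emulates the structure of a real intercomparison study with
every parameter known:

- **Truth landscape** — white Gaussian noise smoothed with a Gaussian
  kernel (`smoothing_sigma`, default 3 px) and thresholded at the
  empirical quantile of the target crop fraction. This gives
  field-patch-like spatial autocorrelation while hitting the target
  fraction to within one pixel of area. Default crop fraction 0.3, within
  the 2–40 % range spanned by the study regions.
- **Degraded products** — optional block-majority aggregation to a coarser
  native grid (ties → non-crop, the dominant-class semantics of coarse
  products) followed by independent per-pixel flips: crop→non-crop with
  probability `omission_rate`, non-crop→crop with `commission_rate`. By
  construction the product's true PA is `1−o` and its true UA is
  `(1−o)f / ((1−o)f + c(1−f))`, so the full pipeline can be validated by
  parameter recovery. The default product set spans 10–1000 m native
  resolutions and nominal years 2009–2020 with error rates growing with
  coarseness, mirroring the spread of public products.
- **Interpreter labels** — each of L ≥ 2 interpreters independently
  reports the truth with probability `1−ε`. The unanimity filter then
  retains a fraction `(1−ε)^L + ε^L` of points in expectation. No
  empirical disagreement rate is available to anchor ε, so it is a free
  parameter (default 0.05, a low-disagreement labeling campaign).
- **NDVI cube** — per-pixel sinusoidal seasonal curves, crop amplitude
  0.35 vs non-crop 0.10 over baselines 0.25/0.30, Gaussian noise sd 0.05,
  23 timesteps (one year of 16-day composites), clipped to [−1, 1]. This
  reproduces the one feature the zonal-series analysis needs — crops
  green up harder at peak season — and nothing else.

What the generator does **not** emulate: multi-class confusion structure
(errors are symmetric flips, not class-specific confusions), spatially
correlated product errors (flips are i.i.d., real product errors cluster
along field boundaries), interpreter correlation (real annotators share
systematic biases), mixed pixels at field edges, clouds, or phenology
beyond a sinusoid. Passing tests therefore demonstrate the correctness of
the estimators and plumbing under the declared error model — not that any
real map meets its nominal accuracy.

## Numerical and engineering choices

- All estimation in double precision; reporting rounds to 2 decimals, and
  output tables carry full-precision and display columns side by side.
- Proportion identities (`ΣW = 1`, `Σp_ij = 1`) enforced to 1e−12; file
  round-trips are value-exact for integers and coordinates (`%.17g`
  formatting with round-trip float parsing).
- Every generator and sampler takes an explicit seed and owns a private
  `numpy` Generator; nothing touches global random state. Pipeline child
  seeds derive from one `SeedSequence`.
- Rasters are exchanged as GeoTIFFs (georeferencing in ModelPixelScale /
  ModelTiepoint tags, nodata 255 for byte rasters); points as GeoJSON or
  flat CSV; tables as CSV. The package assumes one CRS per analysis and
  never reprojects.
- Stratified sampling uses rejection sampling capped at 1,000 batches per
  stratum; a stratum with no eligible pixels yields zero points with a
  warning rather than an error.
- Test problem sizes (landscapes up to 200×200, 2,000 replicates or
  points for the Monte-Carlo checks) were chosen so the closed-form
  targets are resolved to well within the 3-SE/10 % bands being asserted.

## Known limitations

- Binary classes only; the multi-class population error matrix is out of
  scope.
- Variance estimators assume the stratification matches map classes;
  a design stratified on a different covariate (the NDVI-stratified
  design) is estimated with the same formulas, without stratum-specific
  inclusion-probability corrections.
- No significance testing on correlations, no kappa/quantity-allocation
  disagreement, no area-estimation confidence intervals.
- Nearest-neighbour resampling assumes the common grid is at least as
  fine as the products being compared; information is never averaged.
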