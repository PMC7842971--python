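# Methods

This note documents the models and procedures implemented in `forestknn`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic tests do and do not show.

## Data model and raster conventions

All rasters are north-up regular grids with cell-center semantics:
column *j* has center `origin_x + (j + 0.5)·cell_size_x`, row *i* has
center `origin_y − (i + 0.5)·cell_size_y`. Missing cells are NaN in
memory; the `nodata` attribute only records the on-disk sentinel. Two
rasters are *aligned* iff their `GridSpec`s (origin, cell sizes, shape,
CRS id) match; every modeling stage asserts alignment rather than
guessing.

GeoTIFF I/O is built on `tifffile`, writing the ModelPixelScale,
ModelTiepoint and GDAL-NoData tags plus a JSON description holding band
names and the CRS identifier. The CRS is an opaque tag: the package
operates within one coordinate system, and `match_resolution` refuses
cross-CRS inputs rather than silently resampling them. Reprojection, when
needed, belongs upstream in a GDAL-based tool.

### Preprocessing operators

- `match_resolution` resamples at reference cell centers, bilinear (for
  continuous layers) or nearest (for categorical); the caller must state
  which. Bilinear weights are renormalized over the finite support, so a
  target cell is NoData only when its whole support is NoData or outside
  the input footprint.
- `match_extent` is pure index arithmetic on phase-aligned grids
  (cropping/padding, optional masking by the reference's NoData cells);
  misaligned grids are an error, not an implicit resample.
- `focal_multiband` default NoData policy is *propagate* (any NoData in
  the window → NoData), the conservative choice; *ignore* reduces over
  finite values only. Cells NoData in the input remain NoData under both
  policies so masks survive smoothing. The common use case is a 3×3 mean,
  assigning a 90 m × 90 m average to each 30 m cell before modeling.
- `edges` grows NoData regions by a Chebyshev (queen) buffer; square
  buffers compose naturally with square focal windows. Whether the raster
  boundary itself seeds the buffer is a flag (`treat_boundary_as_nodata`,
  default off) rather than a hidden assumption.
- `tile`/`mosaic` are exact inverses for any tiling; tiles carry shifted
  geotransforms.

## Spectral indices

NDVI = (nir−red)/(nir+red), NBR = (nir−swir2)/(nir+swir2), zero
denominators → NoData. Tasseled Cap components are dot products of the six
reflective bands with a versioned coefficient table keyed by sensor tag;
the shipped `landsat5tm` set is Crist's (1985) TM reflectance-factor
coefficients. Inputs are assumed to be surface reflectance on a [0, 1]
scale — TC coefficients are scale-sensitive, and a uniform integer scaling
only rescales the components linearly. Raster and point-table code paths
share the formulas, so extracting-then-computing equals
computing-then-extracting.

## Temporal summary metrics

Each index series is reduced per pixel to median, IQR and Theil–Sen slope
(plus user-registered reducers). Choices:

- **Quantiles** use linear interpolation between order statistics (the
  ubiquitous default; the IQR method is otherwise ambiguous).
- **Theil–Sen** is the median of all pairwise slopes and uses *calendar
  years*, not layer indices, so gappy series still yield slopes per year.
- **min_valid** defaults to 3 finite years: a slope from two points is a
  single pairwise ratio with no median smoothing. Pixels below the
  threshold are NoData.
- Block-wise execution (`block_rows`) bounds memory; outputs are
  bit-identical for any block size because every pixel is reduced
  independently.

## Structure-guided sampling

References are clustered in response space (k-means on per-band
standardized values; standardization is the "normalization" needed before
clustering mixed-unit attributes, with k-means++ seeding and 10 restarts).
Sample quotas per stratum follow largest-remainder apportionment of the
requested n by stratum cell counts — quotas sum to n and are within one
point of exact proportionality. Candidates are visited in seeded random
order and accepted greedily when at least `min_dist` (Euclidean, map
units, between cell centroids) from every accepted point across all
strata; the attempt budget is 50·n candidate visits, after which a stratum
falls short with a logged warning naming the shortfall. This
shortfall-with-warning policy is a deliberate choice: proportional quotas
and a spacing constraint can be jointly infeasible in sparse strata, and a
smaller honest sample beats a constraint violation.

Fold assignment shuffles each stratum (seeded) and deals points
round-robin; the dealing pointer carries across strata, so per-stratum
*and* overall fold sizes differ by at most one (230 points in 5 folds give
exactly 46 held out per fold). Holdout mode keeps at least one test point
per stratum.

## k-NN imputation with random-forest proximity

One regression forest is grown per response variable (`ntree` trees,
`mtry` split candidates; responses are treated as continuous throughout).
The proximity between observations is the proportion of trees — pooled
over all per-response forests — in which both land in the same terminal
node; pooling makes the nearness measure respond to every response
variable at once. Defaults `ntree=200`, `mtry=3`, `k=1` are the
configuration of the worked example.

- **k = 1** copies the nearest reference's full response vector and
  reports its row id, so every imputed vector is a real observation and
  among-attribute relationships survive. **k > 1** takes the simple or
  proximity-weighted mean (`distance_weighted_mean` is the default of the
  two, as the information-preserving choice).
- **Ties** in proximity break to the lowest reference id (stable argsort),
  making maps bit-reproducible.
- **Degenerate targets** with zero proximity to every reference are
  imputed from the lowest-id references with a warning.
- **Alternative metrics**: Euclidean and Mahalanobis distance on the
  predictors are available; whether Mahalanobis covariance is taken on raw
  or standardized predictors is a flag (`mahalanobis_standardized`,
  default raw).
- **Chunked prediction**: `predict_targets` processes `chunk_rows` raster
  rows at a time, and proximities are computed reference-blockwise, so
  peak memory is O(chunk_cells × block × trees) booleans regardless of
  scene size. Output is invariant to chunking and to tile-then-mosaic
  execution. Cells with any NoData predictor are NoData in all output
  bands.

### Accuracy

R² = 1 − SSR/SST (SST about the observed mean; R² may be negative), RMSE,
and bias = mean(predicted − observed), with relative forms as 100·stat /
mean(observed) (undefined with a warning when that mean is zero). Reports
are available pooled or per fold. RMSE ≥ |bias| always holds.

### Variable importance

Per tree, the out-of-bag mean squared error is compared with the error
after permuting one predictor (seeded, one permutation per predictor per
tree by default; repetitions configurable); raw importance is the mean
increase over trees. Within each response the raw values are z-scored
across predictors, so below-average predictors are negative; the mean
z-score across responses summarizes overall usefulness. With one predictor
the z-score is undefined and reported as 0 with a warning; identical raw
importances likewise map to 0.

## Synthetic scenes

`make_scene` builds all inputs on one grid from seeded, spatially
correlated Gaussian fields (white noise smoothed with a Gaussian kernel,
correlation length in cells):

- **Stand structure**: a smooth field thresholded into discrete stand
  types (default 2: young/open vs mature/closed) sets a per-pixel NDVI
  baseline (levels 0.30 and 0.85), plus bounded within-stand variation
  (±0.03). The resulting multimodal response distribution mirrors managed
  forests where distinct stand conditions dominate the variance, and it is
  what gives the imputation model a recoverable signal relative to the
  noise level.
- **Trends**: a bounded field of NDVI slopes (±0.004/yr). Yearly
  reflectance encodes `ndvi(t) = baseline + slope·(t − mid_year)` through
  the red/nir pair, plus per-band noise (sd 0.01). Because the year count
  is odd and the series linear, the noiseless NDVI median equals the
  baseline and the noiseless Theil–Sen slope equals the trend exactly —
  the temporal stage is checkable against truth.
- **Responses**: affine links in (NDVI baseline − 0.575) and standardized
  elevation with a small interaction — canopy height `elev_p95` (~0–44 m)
  and `cover` (~30–90%). Gaussian noise with sd = `noise_sd_frac` × the
  noiseless range (default 0.10) is added, and a smooth forested mask
  hides `mask_fraction` of cells. The truth record stores the link, the
  generating fields and the noiseless responses.
- `make_reference_strips` keeps responses only in vertical strips,
  emulating discontinuous acquisition blocks; everything outside is
  imputation target.

What passing tests show: the pipeline recovers a smooth, multimodal
response surface from noisy annual composites at the stated noise level
(held-out R² ≈ 0.88, |bias%| well under 1 averaged over seeds at desk
scale: 100×100 cells, 230 samples). What they do not show: performance on
real imagery with phenology, clouds, sensor changes, registration error,
or response–predictor relationships weaker or less stationary than the
synthetic link. The synthetic scene is a correctness and sanity harness,
not an accuracy forecast.

## Problem sizes and determinism

Default test and acceptance runs use 100×100-cell scenes, 25-year series,
230 samples and 200-tree forests — sizes chosen so the whole study runs in
seconds while keeping the sampling design (spacing, strata, folds) at its
stated values. Every stochastic step (field generation, k-means, sample
order, fold dealing, forest growth, permutation importance) takes an
explicit seed, and equal seeds give bit-identical artifacts end to end.

## Known limitations

- Same-CRS only; no reprojection or multi-scene mosaicking.
- No variogram-based guidance for choosing `min_dist`; the constraint is
  enforced, not derived.
- Accuracy metrics quantify the imputation model only; uncertainty in the
  reference responses themselves (e.g. the model that produced gridded ALS
  metrics) is not propagated, and no two-stage variance estimator is
  provided.
- The forests are scikit-learn regression forests; proximity is defined by
  terminal-node co-occurrence and will differ in detail from other
  random-forest implementations even at equal settings.
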