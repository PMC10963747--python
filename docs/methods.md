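# Methods

## Agricultural ET as a counterfactual difference

Agricultural ET is defined per pixel as `ET_ag = ET_tot − ET_nat`:
the observed total ET minus the ET the same land would exhibit if fallow.
The counterfactual is estimated, not assumed equal to precipitation,
because precipitation both under-counts (soil moisture carry-over, shallow
groundwater) and over-counts (runoff, winter timing) the water naturally
available to vegetation. Fallow fields expose `ET_nat` directly; a
regression model trained there transfers it to cropped land. The
difference is kept **signed** — negative values are information about
counterfactual error and are retained through all statistics (the
fallowing scenario's replacement rule applies to them exactly as written;
a floor-at-zero sensitivity flag exists but is off by default).

## The counterfactual model

A gradient-boosted tree ensemble predicts monthly fallow ET from
`(x, y, month, year, elevation, aspect, slope, TWI, soil quality, PET)`.
Coordinates are projected meters of the pixel center; month and year enter
as integers (trees need no encoding). Hyperparameters are chosen by
randomized search (default 20 candidates, 3-fold CV) on an unclustered
subsample (default 30 000 rows) of the training partition, then the winner
is refit on the full partition. The search space covers the number of
boosting iterations (200–1000), learning rate (0.05–0.2), tree depth and
leaf count. Two minimum-sample constraints (200 to split a node, 100 per
leaf) are calibrated to a reference training size of 10 M rows and scaled
proportionally for smaller training sets, where they become non-binding.
The default backend is scikit-learn's histogram gradient boosting (fast,
exposes the leaf constraint); the classic exact-split implementation,
which honours both constraints, is selectable via
`model_backend: "classic"`. Predictions are clipped below at zero — an ET
depth cannot be negative. All randomness is seeded; a fitted model carries
its features, chosen parameters, seed and constraint values.

### Training-set screening

Fallow pixel-years whose July+August+September ET sum is strictly above
the 95th percentile of all such sums (pooled across years, linear
interpolation between order statistics) are removed entirely — a high
mid-summer signal on a "fallow" label suggests an actively cropped field.
Pixel-years missing a summer month are exempt and logged. The percentile
is computed on the seasonal sum rather than per month: a seasonal sum is
the natural screen for a field that was active during the growing season,
and one quantile convention (linear interpolation) is used package-wide.

The screen guards against *label contamination*. The synthetic generator
does not inject mislabeled fields, so on synthetic data the screen merely
truncates the upper tail of the legitimate natural-ET distribution —
removing exactly the high-PET, high-gain combinations and slightly biasing
predictions in the warmest band. The model-recovery benchmark therefore
fits without the screen, while the default pipeline keeps it (as real use
requires); its behaviour is verified by its own dedicated tests.

### Spatially blocked splits

Pixels are grouped into square blocks of 2 km side anchored at the
coordinate origin; whole blocks are assigned to train/validation/test at
0.6/0.1/0.3 by largest-remainder counts (so 8 180 blocks give exactly
4 908 / 818 / 2 454) under a seeded permutation. Nearby pixels can never
straddle partitions, which is what makes held-out skill meaningful.

### Validation at the annual scale

All downstream analysis uses annual ET, so the model is scored on
pixel-year sums of held-out blocks: `R² = 1 − SS_res/SS_tot` and MAE in
mm/yr, plus mean residuals by block and by year to reveal structured
error. Pixel-years with fewer than 12 months are excluded and counted.

## Annualization and year adjustment

Annual values are sums of the 12 monthly values; pixel-years missing any
month are excluded by default (a non-strict mode sums what is present).
Year-level shifts are removed by
`Adjusted_py = ET_py − (mean_y − grand mean)`; afterwards every year's
mean equals the grand mean (to 1e-9) and all within-year contrasts are
untouched. A single-year input is an exact fixed point by construction —
the scenario analysis, which uses one year only, relies on this.

## Inference with spatial clustering

Group means (overall, per crop, per county) are the point estimates of a
saturated dummy regression, i.e. exactly the per-group arithmetic means.
Errors are allowed to correlate arbitrarily within square spatial tiles;
the sandwich variance for a group mean reduces to

    SE² = G/(G−1) · Σ_c (Σ_{i∈c} e_i)² / n²

over the G tiles intersecting the group, with 95% intervals at ±1.96·SE
(cluster counts are large; a t quantile would change little). A group
contained in one tile gets a missing SE with a warning. Tile side defaults
to 75 km for continental-scale data — chosen from the empirical variogram
of agricultural ET — and to 2.1 km on the 14 km synthetic region, scaled
the same way: comfortably beyond the within-field correlation the
generator injects (fields are 350 m). The variogram itself is
`γ(h) = ½·mean[(z_i − z_j)²]` over distance-binned pixel pairs,
exhaustively enumerated when feasible and subsampled with a seed
otherwise.

Variance decomposition uses the R² of least-squares fits on crop dummies
or on linear covariates. Covariate control ("what would this pixel consume
at sample-average conditions?") adds the fitted grand mean back to the
residuals, preserving the overall mean exactly. Aspect is circular, so it
enters as sine and cosine by default; a raw-degrees option exists for
literal replication. Exactly collinear columns are tolerated (minimum-norm
least squares; R² is unaffected) and logged.

## Management scenarios

Within each groundwater sub-basin, with `ET_c,b` the mean agricultural ET
of crop c and pixels indexed by i:

- **Crop switching**: every pixel contributes
  `min(ET_c(i),b, Median_b(ET_c,b))`; the median is over the *distinct
  crops'* means, unweighted by area (the literal reading of the
  statistic), with linear interpolation for even counts. A
  switch-to-minimum variant replaces the median by the lowest crop mean —
  the ceiling for land-cover change.
- **Farming practices**: `min(ET_i, T_c(i))` with `T_c` the crop's
  **median** consumption by default (the mean is available via config and
  recorded in the manifest; the defining expression admits either reading
  and the median matches the scenario's narrative of "reducing high
  consumers to the typical level").
- **Fallowing**: pixels strictly above the sub-basin's 95th percentile
  contribute zero.

Savings are `1 − Σ contributions / Σ ET_i`, undefined (and excluded, with
a count) where the baseline sum is non-positive. The regional aggregate is
ET-weighted — pooled numerators over pooled baselines — with the
unweighted mean of fractions reported alongside. Scenario inputs are
single-year, orchard-filtered, covariate-controlled pixels: orchards
bearing fruit for ≤ 5 years or in their final production year are removed
first (young orchards consume systematically less; the boundary age is
removed), and rows lacking age attributes are kept with a warning.

## Irrigation efficiency

`efficiency = ag-ET depth / irrigation depth` per county, both in mm/yr.
Irrigation depth is volume / irrigated area (1 m³ over 1 m² = 1000 mm),
averaged over two configured record years by default (irrigation censuses
rarely coincide with the ET years; every year combination is computable
for sensitivity). All active agricultural land is treated as irrigated.
Counties partly outside the study region are handled by scaling volume
with an `in_region_fraction` column, assuming irrigation is evenly
distributed over the county's irrigated land. The county ag-ET depth is
the cluster-robust group mean of year-adjusted agricultural ET over
cropped pixels, and its CI propagates to an efficiency CI. Values above 1
are flagged, never clipped — they indicate inconsistent inputs.

## The synthetic study region

Defaults: 200×200 pixels at 70 m (14×14 km), 12 months × 3 years
(~1.4 M pixel-months), 6 crops on 5×5-pixel (~12 ha) rectangular fields,
12% of fields fallow (drawn independently per field, hence interspersed),
4 counties, 8 sub-basins — sized to run the full pipeline in minutes on
one CPU.

**Covariates.** TWI, slope and aspect vary at field scale (terrain indices
really do change over tens of meters). PET follows a dominant
north-to-south gradient (hotter southward, as in a long interior valley)
times a July-peaking seasonal cycle, plus weak smooth texture and a small
multiplicative year anomaly. Elevation and soil quality combine a
deterministic cross-valley tilt with rough texture. These choices make
every covariate level occur in many places across the extent, so held-out
blocks are never outside the training support — a property real dense
fallow coverage provides and a blocked evaluation needs.

**Natural ET.** A smooth nonlinear function of the covariates: a convex
(demand-amplifying) PET response times a gain composed of a TWI sigmoid, a
soil-quality term and an elevation penalty, plus a gentle positional
trend, clipped at zero, with iid Gaussian pixel-month noise on top
(default SD 3 mm/month ≈ 10% of the ~30 mm mean monthly natural ET). Two
deliberate properties: the function is nonlinear enough that a pooled
linear fit leaves several-fold larger errors than the tree ensemble, and
the purely positional trend is gentle at the 2 km block scale — inside a
held-out block a tree model can only interpolate from neighbouring
blocks, so position-only variation steeper than the block side would be
irreducible by construction, which is a statement about blocked
evaluation, not about the learner.

**Agricultural increments.** Drawn once per field-year from
`Normal(crop mean, within-crop SD)` truncated at zero (defaults 141–715
mm/yr with SDs 50–160, spanning the range from grain/hay to orchard
crops), spread over April–October with fixed weights. Young orchards
(≤ 5 years bearing) get 40% of their crop mean; a small fraction of
orchard fields is flagged last-year-of-production. Drawing per field-year
(not per pixel) makes within-field pixels correlate, which is what gives
the 2 km blocks and the clustered standard errors something real to do.

**Irrigation table.** County volume = realized mean increment depth ×
irrigated area / configured efficiency (defaults 0.4/0.6/0.8/0.6), per
year; a county with no cropped pixels gets zero area and missing volume.
The efficiency module applied to this table recovers the configured
values exactly when the counterfactual is exact.

**What the generator does not emulate:** real geography and weather
reanalysis, physical soil-water balance, crop rotation, label
contamination of the fallow map, measurement error structure of ET
retrievals beyond iid noise, and irregular field/parcel shapes. Passing
tests therefore demonstrate the *pipeline's* correctness and calibration
under known ground truth, not skill on any real landscape.

## Numerical conventions

- Percentiles/quantiles: linear interpolation between order statistics,
  package-wide; screens and scenario thresholds use strict exceedance, so
  all-tied inputs remove nothing.
- Rasters: float64 GeoTIFF with NaN missing values (bitwise round-trip);
  pixel (0,0) at the upper-left corner, cell values at cell centers.
- Resampling to coarser grids: overlap-area-weighted mean, ignoring NaN
  (ET is an intensive depth; the mean is the meaningful aggregate);
  refusing to "resample" to a finer grid.
- Block/cluster tiles are anchored at the coordinate origin.
- Split counts follow the largest-remainder rule; partitions, model seeds
  and search draws all derive from the run seed, making repeated runs
  byte-identical.

## Known limitations

- The counterfactual transfers fallow-land ET to cropped land; systematic
  fallow-vs-cropped differences beyond the covariates (e.g. farmers
  fallowing their worst land) are only corrected insofar as the
  covariates capture them.
- Scenario savings assume consumption distributions are transferable
  across pixels within a sub-basin and carry no economics; they are upper
  bounds on management potential.
- Pixel-level prediction uncertainty is not quantified; inference is at
  the group-mean level only.
- No CRS reprojection: all inputs must share one projected CRS.
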