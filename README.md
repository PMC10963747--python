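# fallowcast

Field-scale **agricultural evapotranspiration (ET)** from a machine-learned
fallow-land counterfactual, with the downstream analyses water managers ask
for: crop water-intensity estimates with spatially clustered inference,
water-saving management scenarios per groundwater sub-basin, and county
irrigation efficiency.

## The problem

Irrigated agriculture consumes water through ET — water that leaves the
watershed entirely. Remote sensing now maps *total* ET at field scale, but
total ET conflates the water agriculture adds with the ET the land would
have produced anyway from rain, soil moisture and shallow groundwater.
The quantity that matters for management is the difference:

```
ET_ag = ET_tot − ET_nat
```

where `ET_nat` is the counterfactual ET of the same parcel left fallow.
`fallowcast` estimates `ET_nat` by training a gradient-boosted tree
ensemble on observed ET over fallow fields — the places where
naturally-occurring ET is directly visible — using position (x, y), month,
year, topography (elevation, slope, aspect, topographic wetness index),
soil quality and potential ET (PET) as predictors, then predicting over
all cropped land.

Key methodological ingredients, each implemented and tested here:

- **Spatially blocked validation.** Neighbouring pixels are nearly
  identical, so train/validation/test splits assign whole 2 km blocks
  (60/10/30) and skill is scored on held-out blocks at the annual scale.
- **Training-set screening.** Fallow pixel-years in the top 5% of
  July–September ET are removed as probable crop-map mislabels.
- **Year adjustment.** `AdjustedET_py = ET_py − (mean_y − grand mean)`
  removes year-level shifts so analyses capture spatial variation only.
- **Cluster-robust inference.** Group means (by crop or county) come from
  dummy regressions with sandwich standard errors over square spatial
  clusters, sized from an empirical variogram of the residual
  autocorrelation.
- **Management scenarios per sub-basin.** Savings from crop switching
  (to the median or the minimum crop), farming-practice convergence
  (capping each pixel at its crop's central consumption), and fallowing
  the top 5% of consumers — all as fractions of baseline agricultural ET.
- **Irrigation efficiency.** County mean agricultural-ET depth divided by
  irrigation-withdrawal depth (volume / irrigated area, in mm/yr).

Because the original input rasters are large external datasets, the
package ships a **synthetic landscape generator** with full ground truth
(hidden natural-ET function, per-field crop increments, configured county
efficiencies) so that every stage is testable end-to-end on a desktop.

## Worked example

Run the whole pipeline on the default synthetic region (200×200 pixels at
70 m, 3 years of monthly data, 6 crops, 4 counties, 8 sub-basins):

```bash
fallowcast all --seed 1 --out-dir demo_out
```

or stage by stage: `simulate → train → ag-et → stats → scenarios →
efficiency`. Outputs are GeoTIFF rasters, GeoJSON polygons and CSV tables
with a JSON manifest. From a seed-1 run:

- `model/metrics.csv` — held-out annual **R² 0.966**, **MAE 8.8 mm/yr**
  (4 562 test pixel-years): the counterfactual recovers the hidden
  natural-ET surface to well within the injected noise (annual noise
  scale ≈ 10.4 mm).
- `stats/crop_estimates.csv` — per-crop mean agricultural ET with 95%
  cluster-robust CIs; the configured crop increments (141–715 mm/yr) are
  recovered within CI.
- `scenarios/scenario_aggregate.csv` — ET-weighted regional savings:
  crop switching **11.6%**, switch-to-minimum-crop **67.9%**,
  farming practices **9.0%**, fallowing the top 5% **10.0%**.
- `efficiency/efficiency.csv` — county efficiencies recovering the
  configured values (0.4–0.8; mean 0.60).

A savings number of 0.116 means that scenario would reduce the region's
agricultural water consumption by 11.6% relative to baseline.

## Layout

| module | role |
| --- | --- |
| `io_geo` | grids, GeoTIFF/GeoJSON/CSV I/O, area-weighted resampling, run config |
| `synthetic_landscape` | ground-truth study region generator |
| `counterfactual` | fallow training table, cleaning, block splits, model fit/validation |
| `ag_et` | ET difference, annualization, year adjustment, orchard-age filter |
| `spatial_stats` | cluster-robust group means, variance decomposition, covariate control, variogram |
| `scenarios` | the four water-saving scenario statistics and aggregation |
| `efficiency` | irrigation depths and county efficiency |
| `pipeline` / `cli` | artifact-directory stages and the `fallowcast` command |

See `docs/methods.md` for the full model description, parameter defaults
and design choices.
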