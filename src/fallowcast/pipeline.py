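"""Pipeline stages wiring the modules together on an artifact directory.

Each stage reads the on-disk artifacts of the previous one (GeoTIFF rasters,
GeoJSON polygons, CSV tables) and writes its own, so stages can be run
separately from the command line; ``run_all`` threads in-memory objects
through to avoid redundant reloads. Every output directory carries a
manifest (config + seed + version) for provenance.
"""

from __future__ import annotations

import logging
import pickle
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import ag_et, counterfactual, efficiency, scenarios, spatial_stats
from .io_geo import (
    FALLOW,
    RunConfig,
    read_raster,
    write_geojson,
    write_manifest,
    write_raster,
    write_table,
)
from .synthetic_landscape import (
    ETSeries,
    LandscapeTruth,
    generate_et_series,
    generate_irrigation_table,
    generate_landscape,
    pixel_month_table,
)

logger = logging.getLogger("fallowcast")

_STATIC_RASTERS = [
    "elevation",
    "slope",
    "aspect",
    "twi",
    "soil_quality",
    "crop_map",
    "field_id",
    "sub_basin",
    "county",
    "orchard_age",
    "orchard_last_year",
]


def _partition_polygons(labels: np.ndarray, grid) -> list[dict]:
    """One rectangular polygon per contiguous tile label (hull of its cells)."""
    feats = []
    ps = grid.pixel_size
    for lab in np.unique(labels):
        rows, cols = np.nonzero(labels == lab)
        x0 = grid.origin_x + cols.min() * ps
        x1 = grid.origin_x + (cols.max() + 1) * ps
        y1 = grid.origin_y - rows.min() * ps
        y0 = grid.origin_y - (rows.max() + 1) * ps
        feats.append({"id": int(lab), "geometry": box(x0, y0, x1, y1)})
    return feats


def stage_simulate(config: RunConfig, out_dir) -> tuple[LandscapeTruth, ETSeries]:
    """Generate the synthetic study region and write every input layer."""
    out = Path(out_dir)
    truth = generate_landscape(config)
    series = generate_et_series(truth)
    grid = truth.grid

    land = out / "landscape"
    write_raster(land / "elevation.tif", truth.elevation, grid)
    write_raster(land / "slope.tif", truth.slope, grid)
    write_raster(land / "aspect.tif", truth.aspect, grid)
    write_raster(land / "twi.tif", truth.twi, grid)
    write_raster(land / "soil_quality.tif", truth.soil_quality, grid)
    write_raster(land / "crop_map.tif", truth.crop.astype(float), grid)
    write_raster(land / "field_id.tif", truth.field_id.astype(float), grid)
    write_raster(land / "sub_basin.tif", truth.sub_basin.astype(float), grid)
    write_raster(land / "county.tif", truth.county.astype(float), grid)
    write_raster(land / "orchard_age.tif", truth.orchard_age, grid)
    write_raster(land / "orchard_last_year.tif", truth.orchard_last_year, grid)
    for year in series.years:
        pet_y = truth.pet * truth.year_pet_factor[year]
        write_raster(land / f"pet_{year}.tif", pet_y, grid)
        write_raster(out / "et" / f"total_{year}.tif", series.total[year], grid)
        write_raster(out / "truth" / f"natural_{year}.tif", series.natural[year], grid)
    write_geojson(land / "counties.geojson", _partition_polygons(truth.county, grid))
    write_geojson(
        land / "sub_basins.geojson", _partition_polygons(truth.sub_basin, grid)
    )
    write_table(land / "irrigation.csv", generate_irrigation_table(truth, series))
    write_table(out / "truth" / "increments.csv", series.increments)
    write_manifest(out / "manifest.json", config, config.seed)
    config.to_yaml(out / "config.yaml")
    return truth, series


def load_pixel_table(config: RunConfig, out_dir) -> pd.DataFrame:
    """Rebuild the long pixel-month table from the artifact directory."""
    out = Path(out_dir)
    land = out / "landscape"
    grid = config.grid
    static = {}
    for name in _STATIC_RASTERS:
        data, _ = read_raster(land / f"{name}.tif")
        static[name] = data[0]
    x, y = grid.center_arrays()
    base = pd.DataFrame(
        {
            "pixel_id": np.arange(x.size, dtype=np.int64),
            "x": x.ravel(),
            "y": y.ravel(),
            "land_cover": static["crop_map"].ravel().astype(np.int16),
            "field_id": static["field_id"].ravel().astype(np.int64),
            "sub_basin": static["sub_basin"].ravel().astype(np.int64),
            "county": static["county"].ravel().astype(np.int64),
            "elevation": static["elevation"].ravel(),
            "slope": static["slope"].ravel(),
            "aspect": static["aspect"].ravel(),
            "twi": static["twi"].ravel(),
            "soil_quality": static["soil_quality"].ravel(),
            "orchard_age": static["orchard_age"].ravel(),
            "orchard_last_year": static["orchard_last_year"].ravel(),
        }
    )
    frames = []
    for year in config.years:
        pet, _ = read_raster(land / f"pet_{year}.tif")
        total_path = out / "et" / f"total_{year}.tif"
        if not total_path.exists():
            raise FileNotFoundError(f"missing input raster: {total_path}")
        total, _ = read_raster(total_path)
        for m in range(12):
            f = base.copy()
            f["month"] = m + 1
            f["year"] = year
            f["pet_mm"] = pet[m].ravel()
            f["et_mm"] = total[m].ravel()
            frames.append(f)
    return pd.concat(frames, ignore_index=True)


def stage_train(
    config: RunConfig, out_dir, pixels: pd.DataFrame | None = None
) -> counterfactual.CounterfactualModel:
    """Assemble, clean, split and fit the counterfactual model; write metrics."""
    out = Path(out_dir)
    if pixels is None:
        pixels = load_pixel_table(config, out)
    table = counterfactual.assemble_training_table(pixels)
    table, removal = counterfactual.clean_fallow_outliers(
        table, months=config.cleaning_months, percentile=config.cleaning_percentile
    )
    split = counterfactual.block_split(
        table,
        block_m=config.block_m,
        fractions=config.split_fractions,
        seed=config.seed,
    )
    table = counterfactual.apply_split(table, split)
    train = table[table["partition"] == "train"]
    val = table[table["partition"] == "validation"]
    test = table[table["partition"] == "test"]
    model = counterfactual.fit_counterfactual(train, val, config, seed=config.seed)
    report = counterfactual.validate_annual(model, test, block_m=config.block_m)
    logger.info(
        "held-out annual R2 %.3f, MAE %.1f mm/yr (%d pixel-years)",
        report.r2,
        report.mae_mm,
        report.n_pixel_years,
    )
    mdir = out / "model"
    mdir.mkdir(parents=True, exist_ok=True)
    with open(mdir / "model.pkl", "wb") as fh:
        pickle.dump(model, fh)
    write_table(
        mdir / "metrics.csv",
        pd.DataFrame(
            [
                {
                    "annual_r2": report.r2,
                    "annual_mae_mm": report.mae_mm,
                    "n_pixel_years": report.n_pixel_years,
                    "n_excluded": report.n_excluded,
                    **{f"param_{k}": v for k, v in model.params.items()},
                }
            ]
        ),
    )
    write_table(mdir / "residuals_by_year.csv", report.by_year)
    write_table(mdir / "residuals_by_block.csv", report.by_block)
    write_table(mdir / "removal_report.csv", pd.DataFrame([removal]))
    write_table(
        mdir / "split.csv",
        split.assignment.rename_axis("block").reset_index(),
    )
    write_table(mdir / "search.csv", model.search_results)
    return model


def load_model(out_dir) -> counterfactual.CounterfactualModel:
    path = Path(out_dir) / "model" / "model.pkl"
    if not path.exists():
        raise FileNotFoundError(f"missing model file: {path} (run `train` first)")
    with open(path, "rb") as fh:
        return pickle.load(fh)


def stage_ag_et(
    config: RunConfig,
    out_dir,
    model=None,
    pixels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Predict natural ET everywhere, annualize and year-adjust; write tables."""
    out = Path(out_dir)
    if model is None:
        model = load_model(out)
    if pixels is None:
        pixels = load_pixel_table(config, out)
    pixels = pixels.copy()
    pixels["et_nat_mm"] = counterfactual.predict_natural_et(model, pixels)
    annual = ag_et.annualize(pixels, strict=True)
    annual = ag_et.year_adjust(annual, col="et_ag_mm")
    write_table(out / "annual" / "annual_pixels.csv", annual)
    grid = config.grid
    for year in config.years:
        sub = annual[annual["year"] == year]
        raster = np.full(grid.n_rows * grid.n_cols, np.nan)
        raster[sub["pixel_id"].to_numpy()] = sub["et_ag_mm"].to_numpy()
        write_raster(
            out / "annual" / f"et_ag_{year}.tif", raster.reshape(grid.shape), grid
        )
    return annual


def load_annual(out_dir) -> pd.DataFrame:
    path = Path(out_dir) / "annual" / "annual_pixels.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing annual table: {path} (run `ag-et` first)")
    return pd.read_csv(path)


def stage_stats(
    config: RunConfig, out_dir, annual: pd.DataFrame | None = None
) -> dict:
    """Crop-mean estimates, variance decomposition and variogram; write CSVs."""
    out = Path(out_dir)
    if annual is None:
        annual = load_annual(out)
    cropped = annual[annual["land_cover"] != FALLOW]
    overall = spatial_stats.group_mean_regression(
        cropped, by=None, cluster_m=config.cluster_m
    )
    by_crop = spatial_stats.group_mean_regression(
        cropped, by="land_cover", cluster_m=config.cluster_m
    )
    r2_crop = spatial_stats.variance_explained(cropped, grouping="land_cover")
    r2_env = spatial_stats.variance_explained(
        cropped,
        covariates=spatial_stats.COVARIATES,
        aspect_circular=config.aspect_circular,
    )
    vario = spatial_stats.empirical_variogram(
        cropped.sample(min(len(cropped), 20000), random_state=config.seed),
        max_lag_m=min(config.n_rows, config.n_cols) * config.pixel_size / 2,
        seed=config.seed,
    )
    sdir = out / "stats"
    write_table(sdir / "overall_mean.csv", overall)
    write_table(sdir / "crop_estimates.csv", by_crop)
    write_table(
        sdir / "variance_explained.csv",
        pd.DataFrame(
            [
                {"regressors": "crop", "r2": r2_crop},
                {"regressors": "climate+topography+soil", "r2": r2_env},
            ]
        ),
    )
    write_table(sdir / "variogram.csv", vario)
    return {"overall": overall, "by_crop": by_crop, "r2_crop": r2_crop, "r2_env": r2_env}


def stage_scenarios(
    config: RunConfig, out_dir, annual: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Orchard-filter, covariate-adjust and evaluate the four scenarios."""
    out = Path(out_dir)
    if annual is None:
        annual = load_annual(out)
    year = config.scenario_year or max(config.years)
    one_year = annual[(annual["year"] == year) & (annual["land_cover"] != FALLOW)]
    filtered, report = ag_et.filter_orchard_age(one_year, config.orchard_crop_codes)
    # single year: year-adjusted equals raw, so control directly on et_ag_mm
    adjusted = spatial_stats.covariate_adjust(
        filtered,
        value="et_ag_mm",
        out_col="et_ag_ctrl_mm",
        aspect_circular=config.aspect_circular,
    )
    table, agg = scenarios.run_scenarios(
        adjusted,
        value="et_ag_ctrl_mm",
        central=config.scenario_central,
        fallow_percentile=config.fallow_percentile,
    )
    sdir = out / "scenarios"
    write_table(sdir / "scenario_results.csv", table)
    write_table(sdir / "scenario_aggregate.csv", agg)
    write_table(sdir / "orchard_filter_report.csv", pd.DataFrame([report]))
    return table, agg


def stage_efficiency(
    config: RunConfig, out_dir, annual: pd.DataFrame | None = None
) -> pd.DataFrame:
    """County irrigation efficiency from annual ag ET and irrigation records."""
    out = Path(out_dir)
    if annual is None:
        annual = load_annual(out)
    irr_path = out / "landscape" / "irrigation.csv"
    if not irr_path.exists():
        raise FileNotFoundError(f"missing input table: {irr_path}")
    irrigation = pd.read_csv(irr_path)
    years = config.irrigation_years or sorted(config.years)[:2]
    table = efficiency.compute_efficiency(
        annual, irrigation, cluster_m=config.cluster_m, years=years
    )
    write_table(out / "efficiency" / "efficiency.csv", table)
    return table


def run_all(config: RunConfig, out_dir) -> dict:
    """The whole pipeline, reusing in-memory objects between stages."""
    truth, series = stage_simulate(config, out_dir)
    pixels = pixel_month_table(truth, series)
    model = stage_train(config, out_dir, pixels=pixels)
    annual = stage_ag_et(config, out_dir, model=model, pixels=pixels)
    stats = stage_stats(config, out_dir, annual=annual)
    scen_table, scen_agg = stage_scenarios(config, out_dir, annual=annual)
    eff = stage_efficiency(config, out_dir, annual=annual)
    return {
        "model": model,
        "annual": annual,
        "stats": stats,
        "scenarios": (scen_table, scen_agg),
        "efficiency": eff,
    }
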