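"""Synthetic study region with known ground truth.

The generator emulates the statistical structure the pipeline assumes: a
smooth naturally-occurring ET field driven by climate (monthly PET),
topography and soils plus pixel noise; contiguous rectangular fields, a
fraction of them fallow and interspersed across the extent; crop-specific
agricultural ET increments drawn once per field-year so that pixels within a
field are correlated; and county irrigation volumes consistent with a
configured irrigation efficiency. Every hidden quantity (the noiseless
natural-ET function, the per-field increments) is retained so recovery can
be tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io_geo import FALLOW, Grid, RunConfig

logger = logging.getLogger("fallowcast")

#: Calendar-month PET climatology shape: peaks in July, low in winter.
MONTHS = np.arange(1, 13)
_PET_SEASON = 60.0 + 55.0 * np.cos(2.0 * np.pi * (MONTHS - 7) / 12.0)

#: Share of the annual agricultural increment applied in each month
#: (growing season April-October).
GROWING_SEASON_WEIGHTS = np.zeros(12)
GROWING_SEASON_WEIGHTS[3:10] = [0.05, 0.10, 0.17, 0.21, 0.19, 0.16, 0.12]


@dataclass
class LandscapeTruth:
    """Full description of a synthetic region, including hidden truth."""

    grid: Grid
    config: RunConfig
    elevation: np.ndarray  # m
    slope: np.ndarray  # deg
    aspect: np.ndarray  # deg
    twi: np.ndarray  # unitless
    soil_quality: np.ndarray  # 0-100 index
    pet: np.ndarray  # (12, rows, cols) mm/month climatology
    field_id: np.ndarray  # int per pixel
    crop: np.ndarray  # land-cover code per pixel; 0 = FALLOW
    sub_basin: np.ndarray  # int per pixel
    county: np.ndarray  # int per pixel
    orchard_age: np.ndarray  # years bearing fruit (NaN if not orchard)
    orchard_last_year: np.ndarray  # 1.0 if final production year (NaN if not orchard)
    year_pet_factor: dict  # year -> multiplicative PET anomaly

    @property
    def n_fields(self) -> int:
        return int(self.field_id.max()) + 1

    def natural_et_function(self, year: int) -> np.ndarray:
        """The noiseless naturally-occurring ET surface, (12, rows, cols) mm.

        A smooth nonlinear blend of PET with a TWI sigmoid, a soil-quality
        interaction, an elevation penalty and a low-frequency spatial trend
        — learnable by a tree ensemble but underfit by a linear model.
        """
        cfg = self.config
        x, y = self.grid.center_arrays()
        lx = cfg.n_cols * cfg.pixel_size
        ly = cfg.n_rows * cfg.pixel_size
        twi_s = 1.0 / (1.0 + np.exp(-(self.twi - 7.0) / 1.5))
        soil_n = self.soil_quality / 100.0
        elev_n = self.elevation / 500.0
        gain = 0.32 + 0.16 * twi_s + 0.08 * soil_n - 0.05 * elev_n
        # The purely positional trend stays gentle at the 2 km block scale:
        # within a held-out block the model can only interpolate from
        # neighbouring blocks, so position-only variation steeper than the
        # block side would be irreducible error by construction.
        trend = (
            1.0 * np.sin(np.pi * x / lx) * np.cos(np.pi * y / ly)
            + 1.5 * (x / lx)
        )
        pet_y = self.pet * self.year_pet_factor[year]
        # convex PET response: natural ET responds more than proportionally
        # in high-demand months (bare/sparse soil dries the fastest in
        # winter but retains moisture that high summer demand can still tap)
        pet_eff = pet_y * (0.8 + 0.4 / (1.0 + np.exp(-(pet_y - 55.0) / 20.0)))
        nat = pet_eff * gain[None, :, :] + trend[None, :, :] + 2.0
        return np.clip(nat, 0.0, None)


def _smooth_field(rng, shape, sigma, lo, hi):
    """Low-frequency random surface rescaled to [lo, hi]."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    rmin, rmax = raw.min(), raw.max()
    if rmax - rmin < 1e-12:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (raw - rmin) / (rmax - rmin) * (hi - lo)


def _partition_map(n_rows, n_cols, tile_rows, tile_cols) -> np.ndarray:
    """Label pixels by rectangular tiles, row-major tile order."""
    r = np.arange(n_rows)[:, None] // tile_rows
    c = np.arange(n_cols)[None, :] // tile_cols
    n_tile_cols = -(-n_cols // tile_cols)
    return (r * n_tile_cols + c).astype(np.int32)


def generate_landscape(config: RunConfig) -> LandscapeTruth:
    """Build covariates, fields, crops and administrative partitions.

    Fallow fields are assigned independently per field with probability
    ``fallow_fraction``, so they are interspersed across the whole extent —
    the counterfactual model must interpolate between them, as it does on
    real crop maps.
    """
    if not 0.0 < config.fallow_fraction < 1.0:
        raise ValueError("fallow_fraction must be strictly between 0 and 1")
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    shape = grid.shape

    # Terrain-driven covariates vary at field scale (TWI and slope really do
    # change over tens of meters). Elevation and soil quality combine a
    # deterministic cross-valley tilt with rough texture, so every level of
    # each covariate occurs in many places across the extent rather than in
    # one unique patch — as on a real valley floor.
    col_frac = np.broadcast_to(
        (np.arange(config.n_cols) / max(config.n_cols - 1, 1))[None, :], shape
    )
    elevation = 10.0 + 300.0 * col_frac + _smooth_field(rng, shape, sigma=8, lo=0.0, hi=190.0)
    slope = _smooth_field(rng, shape, sigma=4, lo=0.0, hi=15.0)
    aspect = _smooth_field(rng, shape, sigma=4, lo=0.0, hi=360.0)
    twi = _smooth_field(rng, shape, sigma=5, lo=2.0, hi=12.0)
    soil_quality = (
        20.0 + 50.0 * (1.0 - col_frac) + _smooth_field(rng, shape, sigma=8, lo=0.0, hi=30.0)
    )

    # Monthly PET climatology: seasonal cycle scaled by a dominant
    # north-to-south gradient (hotter toward the bottom of the grid, as in
    # a Central-Valley-like region) plus weak smooth texture.
    row_frac = (np.arange(config.n_rows) / max(config.n_rows - 1, 1))[:, None]
    pet_mod = (
        0.70
        + 0.6 * np.broadcast_to(row_frac, shape)
        + _smooth_field(rng, shape, sigma=20, lo=-0.06, hi=0.06)
    )
    pet = _PET_SEASON[:, None, None] * pet_mod[None, :, :]

    field_id = _partition_map(*shape, config.field_rows, config.field_cols)
    n_fields = int(field_id.max()) + 1

    fallow = rng.random(n_fields) < config.fallow_fraction
    crop_of_field = rng.integers(1, config.n_crops + 1, size=n_fields)
    crop_of_field[fallow] = FALLOW
    crop = crop_of_field[field_id]

    # orchard attributes per field (NaN for non-orchard fields)
    orchard_age_f = np.full(n_fields, np.nan)
    last_year_f = np.full(n_fields, np.nan)
    is_orchard = np.isin(crop_of_field, config.orchard_crop_codes)
    n_orch = int(is_orchard.sum())
    if n_orch:
        young = rng.random(n_orch) < config.young_orchard_prob
        ages = np.where(
            young, rng.integers(1, 6, size=n_orch), rng.integers(6, 31, size=n_orch)
        )
        orchard_age_f[is_orchard] = ages
        last_year_f[is_orchard] = (rng.random(n_orch) < config.last_year_prob).astype(
            float
        )
    orchard_age = orchard_age_f[field_id]
    orchard_last_year = last_year_f[field_id]

    county = _partition_map(
        *shape,
        -(-config.n_rows // config.n_county_rows),
        -(-config.n_cols // config.n_county_cols),
    )
    sub_basin = _partition_map(
        *shape,
        -(-config.n_rows // config.n_subbasin_rows),
        -(-config.n_cols // config.n_subbasin_cols),
    )

    year_pet_factor = {
        y: f for y, f in zip(config.years, (0.95, 1.0, 1.05, 0.9, 1.1, 1.02))
    }
    for y in config.years:
        year_pet_factor.setdefault(y, 1.0)

    return LandscapeTruth(
        grid=grid,
        config=config,
        elevation=elevation,
        slope=slope,
        aspect=aspect,
        twi=twi,
        soil_quality=soil_quality,
        pet=pet,
        field_id=field_id,
        crop=crop,
        sub_basin=sub_basin,
        county=county,
        orchard_age=orchard_age,
        orchard_last_year=orchard_last_year,
        year_pet_factor=year_pet_factor,
    )


@dataclass
class ETSeries:
    """Monthly ET stacks per year plus the hidden construction pieces."""

    years: list
    total: dict  # year -> (12, rows, cols) mm/month
    natural: dict  # year -> (12, rows, cols) mm/month (includes noise)
    increments: pd.DataFrame  # field_id, year, crop, increment_mm (annual)


def generate_et_series(truth: LandscapeTruth, years=None) -> ETSeries:
    """Simulate total and naturally-occurring monthly ET.

    Natural ET = noiseless smooth function + iid Gaussian pixel-month noise.
    Total ET = natural ET + the field's annual agricultural increment spread
    over growing-season months. Increments are drawn once per field-year
    from Normal(crop mean, within-crop SD) truncated at zero; young orchards
    get ``young_orchard_et_fraction`` of their crop mean instead.
    """
    cfg = truth.config
    years = list(cfg.years if years is None else years)
    if not years:
        raise ValueError("years list is empty")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 424243]))
    n_fields = truth.n_fields
    crop_of_field = np.zeros(n_fields, dtype=int)
    np.put(crop_of_field, truth.field_id.ravel(), truth.crop.ravel())

    means = np.asarray(cfg.crop_et_mean_mm, dtype=float)
    sds = np.asarray(cfg.crop_et_sd_mm, dtype=float)
    if np.any(means < 0):
        raise ValueError("crop ET means must be >= 0")

    total, natural = {}, {}
    inc_rows = []
    for year in years:
        nat = truth.natural_et_function(year)
        if cfg.noise_sd_mm > 0:
            nat = nat + rng.normal(0.0, cfg.noise_sd_mm, size=nat.shape)
        nat = np.clip(nat, 0.0, None)

        inc_f = np.zeros(n_fields)
        cropped = crop_of_field > 0
        idx = crop_of_field[cropped] - 1
        draw = rng.normal(means[idx], sds[idx])
        young = (
            np.isin(crop_of_field[cropped], cfg.orchard_crop_codes)
            & (orchard_young(truth)[cropped])
        )
        draw[young] = means[idx][young] * cfg.young_orchard_et_fraction
        inc_f[cropped] = np.clip(draw, 0.0, None)

        inc_pixel = inc_f[truth.field_id]
        tot = nat + GROWING_SEASON_WEIGHTS[:, None, None] * inc_pixel[None, :, :]
        total[year] = tot
        natural[year] = nat
        inc_rows.append(
            pd.DataFrame(
                {
                    "field_id": np.arange(n_fields),
                    "year": year,
                    "crop": crop_of_field,
                    "increment_mm": inc_f,
                }
            )
        )
    increments = pd.concat(inc_rows, ignore_index=True)
    return ETSeries(years=years, total=total, natural=natural, increments=increments)


def orchard_young(truth: LandscapeTruth) -> np.ndarray:
    """Per-field flag: orchard bearing fruit for 5 or fewer years."""
    age_f = np.full(truth.n_fields, np.nan)
    np.put(age_f, truth.field_id.ravel(), truth.orchard_age.ravel())
    with np.errstate(invalid="ignore"):
        return age_f <= 5


def generate_irrigation_table(truth: LandscapeTruth, series: ETSeries) -> pd.DataFrame:
    """County withdrawal volumes consistent with the configured efficiencies.

    volume = (county mean agricultural-ET depth x irrigated area) / efficiency,
    where the agricultural-ET depth is the realized per-pixel increment and
    irrigated area is the area of non-fallow pixels. A county with no cropped
    pixels gets a row with zero area and missing volume.
    """
    cfg = truth.config
    eff = np.asarray(cfg.county_efficiency, dtype=float)
    if np.any(eff <= 0) or np.any(eff > 1):
        raise ValueError("county efficiencies must be in (0, 1]")
    px_area = truth.grid.pixel_size**2
    counties = np.unique(truth.county)
    inc = series.increments
    rows = []
    for year in series.years:
        inc_f = (
            inc[inc["year"] == year].set_index("field_id")["increment_mm"].to_numpy()
        )
        inc_pixel = inc_f[truth.field_id]
        for county in counties:
            in_county = truth.county == county
            cropped = in_county & (truth.crop != FALLOW)
            n_cropped = int(cropped.sum())
            area = n_cropped * px_area
            if n_cropped == 0:
                volume = np.nan
                logger.warning("county %d has no cropped pixels", county)
            else:
                depth_mm = float(inc_pixel[cropped].mean())
                e = eff[county % len(eff)]
                # mm * m^2 -> m^3 via /1000
                volume = depth_mm / 1000.0 * area / e
            rows.append(
                {
                    "county_id": int(county),
                    "year": int(year),
                    "volume_m3": volume,
                    "irrigated_area_m2": area,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabular views
# ---------------------------------------------------------------------------

_STATIC_COLS = [
    "pixel_id",
    "x",
    "y",
    "land_cover",
    "field_id",
    "sub_basin",
    "county",
    "elevation",
    "slope",
    "aspect",
    "twi",
    "soil_quality",
    "orchard_age",
    "orchard_last_year",
]


def static_pixel_frame(truth: LandscapeTruth) -> pd.DataFrame:
    """One row per pixel with coordinates, labels and static covariates."""
    x, y = truth.grid.center_arrays()
    return pd.DataFrame(
        {
            "pixel_id": np.arange(x.size, dtype=np.int64),
            "x": x.ravel(),
            "y": y.ravel(),
            "land_cover": truth.crop.ravel().astype(np.int16),
            "field_id": truth.field_id.ravel(),
            "sub_basin": truth.sub_basin.ravel(),
            "county": truth.county.ravel(),
            "elevation": truth.elevation.ravel(),
            "slope": truth.slope.ravel(),
            "aspect": truth.aspect.ravel(),
            "twi": truth.twi.ravel(),
            "soil_quality": truth.soil_quality.ravel(),
            "orchard_age": truth.orchard_age.ravel(),
            "orchard_last_year": truth.orchard_last_year.ravel(),
        }
    )


def annual_truth_frame(truth: LandscapeTruth, series: ETSeries) -> pd.DataFrame:
    """Annual pixel table using the hidden natural-ET stack as counterfactual.

    Since total = natural + increment by construction, the resulting
    ``et_ag_mm`` equals each field's drawn annual increment exactly; this is
    the ground-truth target the model-based pipeline tries to recover.
    """
    static = static_pixel_frame(truth)
    frames = []
    for year in series.years:
        f = static.copy()
        f["year"] = year
        f["et_mm"] = series.total[year].sum(axis=0).ravel()
        f["et_nat_mm"] = series.natural[year].sum(axis=0).ravel()
        f["et_ag_mm"] = f["et_mm"] - f["et_nat_mm"]
        f["pet_mm"] = (truth.pet * truth.year_pet_factor[year]).mean(axis=0).ravel()
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def pixel_month_table(
    truth: LandscapeTruth,
    series: ETSeries,
    include_natural: bool = False,
) -> pd.DataFrame:
    """Long-format pixel-month observations for the whole region.

    Columns: the static pixel frame plus month, year, pet_mm and et_mm
    (total ET); with ``include_natural`` the hidden natural ET is attached
    as ``et_nat_true_mm`` (used only by tests and truth outputs).
    """
    static = static_pixel_frame(truth)
    n_px = len(static)
    frames = []
    for year in series.years:
        pet_y = truth.pet * truth.year_pet_factor[year]
        for m in range(12):
            f = static.copy()
            f["month"] = m + 1
            f["year"] = year
            f["pet_mm"] = pet_y[m].ravel()
            f["et_mm"] = series.total[year][m].ravel()
            if include_natural:
                f["et_nat_true_mm"] = series.natural[year][m].ravel()
            frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    assert len(out) == n_px * 12 * len(series.years)
    return out
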