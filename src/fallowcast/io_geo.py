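"""Raster/vector/table I/O, grid geometry, resampling, and run configuration.

All coordinates are projected meters. Pixel indices are 0-based, row-major,
with the origin at the upper-left corner of the grid; a cell's value refers
to its center. Rasters are GeoTIFFs (band = month for monthly stacks) with
georeferencing carried in the standard ModelPixelScale / ModelTiepoint tags;
missing data is NaN on disk and in memory, never a numeric sentinel.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import yaml

import tifffile

logger = logging.getLogger("fallowcast")

#: GeoTIFF tag codes for the affine georeferencing we read and write.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_ASCII = 34737  # carries the CRS label

FALLOW = 0  # land-cover code for fallow fields; crops are 1..n_crops


# ---------------------------------------------------------------------------
# Grid geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """A north-up, axis-aligned raster grid in projected meters.

    ``origin_x``/``origin_y`` locate the upper-left *corner* of pixel (0, 0);
    y decreases with increasing row index.
    """

    origin_x: float
    origin_y: float
    pixel_size: float
    n_rows: int
    n_cols: int
    crs_label: str = "local-meters"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the grid footprint."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_size,
            self.origin_x + self.n_cols * self.pixel_size,
            self.origin_y,
        )

    def cell_center(self, row, col):
        """Center coordinates of pixel (row, col); accepts arrays."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.pixel_size
        y = self.origin_y - (row + 0.5) * self.pixel_size
        return x, y

    def center_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates for every cell, each of shape (rows, cols)."""
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return self.cell_center(rows, cols)

    def row_edges(self) -> np.ndarray:
        """y coordinates of horizontal cell edges, descending, length n_rows+1."""
        return self.origin_y - np.arange(self.n_rows + 1) * self.pixel_size

    def col_edges(self) -> np.ndarray:
        """x coordinates of vertical cell edges, ascending, length n_cols+1."""
        return self.origin_x + np.arange(self.n_cols + 1) * self.pixel_size


# ---------------------------------------------------------------------------
# Raster I/O (GeoTIFF via tifffile, with standard geo-tags)
# ---------------------------------------------------------------------------

def write_raster(path, data: np.ndarray, grid: Grid, nodata=np.nan) -> None:
    """Write a (rows, cols) or (bands, rows, cols) array as a GeoTIFF.

    Values are stored as float64 so a write -> read round trip is bitwise
    exact. ``nodata`` values are converted to NaN on disk.
    """
    path = Path(path)
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError("raster data must be 2-D or 3-D (bands, rows, cols)")
    if data.shape[1:] != grid.shape:
        raise ValueError(
            f"data shape {data.shape[1:]} does not match grid {grid.shape}"
        )
    if nodata is not None and not np.isnan(nodata):
        data = np.where(data == nodata, np.nan, data)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.pixel_size, grid.pixel_size, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0), True),
        (_TAG_GEO_ASCII, "s", 0, grid.crs_label, True),
    ]
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data, photometric="minisblack", extratags=extratags)


def read_raster(path) -> tuple[np.ndarray, Grid]:
    """Read a GeoTIFF written by :func:`write_raster` (or compatible).

    Returns ``(data, grid)`` where data has shape (bands, rows, cols) and
    nodata is NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(np.float64)
        page = tif.pages[0]
        tags = {t.code: t.value for t in page.tags.values()}
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"raster {path} lacks georeferencing tags")
        scale = tags[_TAG_PIXEL_SCALE]
        tiepoint = tags[_TAG_TIEPOINT]
        crs_label = (tags.get(_TAG_GEO_ASCII) or "local-meters").rstrip("|")
    if data.ndim == 2:
        data = data[None, :, :]
    grid = Grid(
        origin_x=float(tiepoint[3]),
        origin_y=float(tiepoint[4]),
        pixel_size=float(scale[0]),
        n_rows=data.shape[1],
        n_cols=data.shape[2],
        crs_label=crs_label,
    )
    return data, grid


def read_raster_stack(path_list: Sequence, grid: Grid) -> np.ndarray:
    """Read several rasters and align them pixel-for-pixel onto ``grid``.

    Each source must share the grid's CRS label and pixel size, be aligned to
    its cell edges, and cover its full extent; larger sources are windowed.
    Returns an array of shape (n_layers_total_bands, rows, cols).
    """
    layers = []
    for path in path_list:
        try:
            data, src = read_raster(path)
        except FileNotFoundError:
            raise FileNotFoundError(f"missing raster layer: {path}")
        if src.crs_label != grid.crs_label:
            raise ValueError(
                f"CRS mismatch for layer {path}: "
                f"{src.crs_label!r} != {grid.crs_label!r}"
            )
        if not np.isclose(src.pixel_size, grid.pixel_size):
            raise ValueError(
                f"pixel size mismatch for layer {path}: "
                f"{src.pixel_size} != {grid.pixel_size}"
            )
        col_off = (grid.origin_x - src.origin_x) / grid.pixel_size
        row_off = (src.origin_y - grid.origin_y) / grid.pixel_size
        if not (
            np.isclose(col_off, round(col_off)) and np.isclose(row_off, round(row_off))
        ):
            raise ValueError(f"layer {path} is not aligned to the target grid")
        col_off = int(round(col_off))
        row_off = int(round(row_off))
        if (
            col_off < 0
            or row_off < 0
            or col_off + grid.n_cols > src.n_cols
            or row_off + grid.n_rows > src.n_rows
        ):
            raise ValueError(f"layer {path} does not cover the target grid extent")
        layers.append(
            data[:, row_off : row_off + grid.n_rows, col_off : col_off + grid.n_cols]
        )
    return np.concatenate(layers, axis=0)


def resample_mean(data: np.ndarray, src: Grid, target: Grid) -> np.ndarray:
    """Aggregate a raster to a coarser grid by area-weighted mean.

    Each target cell is the overlap-area-weighted mean of the source cells
    under its footprint, ignoring NaN cells; a target cell whose footprint is
    entirely NaN (or uncovered) is NaN. ET is a depth (intensive), so the
    mean — not the sum — is the physically meaningful aggregate.
    """
    if target.pixel_size < src.pixel_size - 1e-9:
        raise ValueError("target grid is finer than the source; cannot aggregate")
    data = np.asarray(data, dtype=np.float64)
    squeeze = data.ndim == 2
    if squeeze:
        data = data[None]

    def _overlap(t_edges_lo, t_edges_hi, s_edges_lo, s_edges_hi):
        # pairwise interval overlap length, shape (n_target, n_source)
        lo = np.maximum(t_edges_lo[:, None], s_edges_lo[None, :])
        hi = np.minimum(t_edges_hi[:, None], s_edges_hi[None, :])
        return np.clip(hi - lo, 0.0, None)

    # rows: y intervals (descending edges)
    t_ry = target.row_edges()
    s_ry = src.row_edges()
    w_rows = _overlap(t_ry[1:], t_ry[:-1], s_ry[1:], s_ry[:-1])
    # cols: x intervals (ascending edges)
    t_cx = target.col_edges()
    s_cx = src.col_edges()
    w_cols = _overlap(t_cx[:-1], t_cx[1:], s_cx[:-1], s_cx[1:])

    valid = np.isfinite(data)
    filled = np.where(valid, data, 0.0)
    out = np.empty((data.shape[0], target.n_rows, target.n_cols))
    for b in range(data.shape[0]):
        num = w_rows @ filled[b] @ w_cols.T
        den = w_rows @ valid[b].astype(np.float64) @ w_cols.T
        with np.errstate(invalid="ignore"):
            out[b] = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# Vector and table I/O
# ---------------------------------------------------------------------------

def write_geojson(path, features: Iterable[dict]) -> None:
    """Write a GeoJSON FeatureCollection. ``features`` are mapping dicts with
    shapely geometries (or GeoJSON geometry dicts) under ``geometry``."""
    from shapely.geometry import mapping

    out = []
    for feat in features:
        geom = feat["geometry"]
        if hasattr(geom, "geom_type"):
            geom = mapping(geom)
        out.append(
            {
                "type": "Feature",
                "geometry": geom,
                "properties": {k: v for k, v in feat.items() if k != "geometry"},
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": out}, fh, indent=1)


def write_table(path, frame) -> None:
    """CSV with header row, UTF-8, '.' decimal — the package's table format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def _default_search_space() -> dict:
    return {
        "max_iter": [200, 500, 1000],
        "learning_rate": [0.05, 0.1, 0.2],
        "max_depth": [None, 4, 8],
        "max_leaf_nodes": [15, 31, 63],
    }


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML.

    The landscape defaults describe the synthetic study region: 200x200
    pixels at 70 m, 12 months x 3 years, 4 counties, 8 groundwater
    sub-basins, 6 crops with fields of 5x5 pixels (~12 ha).
    """

    # grid
    n_rows: int = 200
    n_cols: int = 200
    pixel_size: float = 70.0
    origin_x: float = 0.0
    origin_y: float | None = None  # defaults to n_rows * pixel_size
    crs_label: str = "local-meters"

    # landscape
    years: list = field(default_factory=lambda: [2016, 2018, 2019])
    n_crops: int = 6
    fallow_fraction: float = 0.12
    field_rows: int = 5
    field_cols: int = 5
    n_county_rows: int = 2
    n_county_cols: int = 2
    n_subbasin_rows: int = 2
    n_subbasin_cols: int = 4
    crop_et_mean_mm: list = field(
        default_factory=lambda: [650.0, 715.0, 480.0, 300.0, 550.0, 141.0]
    )
    crop_et_sd_mm: list = field(
        default_factory=lambda: [130.0, 160.0, 100.0, 80.0, 110.0, 50.0]
    )
    orchard_crop_codes: list = field(default_factory=lambda: [1, 2])
    young_orchard_prob: float = 0.2
    young_orchard_et_fraction: float = 0.4
    last_year_prob: float = 0.05
    noise_sd_mm: float = 3.0
    county_efficiency: list = field(default_factory=lambda: [0.4, 0.6, 0.8, 0.6])

    # counterfactual model
    model_backend: str = "hist"  # "hist" or "classic"
    split_fractions: tuple = (0.6, 0.1, 0.3)
    block_m: float = 2000.0
    n_search_candidates: int = 20
    search_cv_folds: int = 3
    search_subsample: int = 30000
    reference_train_size: int = 10_000_000
    min_samples_split: int = 200
    min_samples_leaf: int = 100
    search_space: dict = field(default_factory=_default_search_space)
    cleaning_percentile: float = 95.0
    cleaning_months: tuple = (7, 8, 9)

    # statistics / scenarios / efficiency
    cluster_m: float = 2100.0  # 75 km on the California-scale data
    scenario_central: str = "median"  # Eq.-7 central statistic
    fallow_percentile: float = 95.0
    scenario_year: int | None = None  # default: last year in `years`
    irrigation_years: list | None = None  # default: first two years
    aspect_circular: bool = True

    seed: int = 0

    def __post_init__(self) -> None:
        if self.origin_y is None:
            self.origin_y = self.n_rows * self.pixel_size
        fr = np.asarray(self.split_fractions, dtype=float)
        if np.any(fr <= 0) or not np.isclose(fr.sum(), 1.0):
            raise ValueError("split fractions must be positive and sum to 1")
        if self.block_m <= self.pixel_size:
            raise ValueError("block size must exceed the pixel size")
        if not 0.0 < self.fallow_fraction < 1.0:
            raise ValueError("fallow_fraction must be strictly between 0 and 1")
        self.split_fractions = tuple(float(f) for f in fr)

    @property
    def grid(self) -> Grid:
        return Grid(
            origin_x=self.origin_x,
            origin_y=float(self.origin_y),
            pixel_size=self.pixel_size,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            crs_label=self.crs_label,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        d["cleaning_months"] = list(self.cleaning_months)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        if "cleaning_months" in d:
            d["cleaning_months"] = tuple(d["cleaning_months"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def write_manifest(path, config: RunConfig, seed: int, extra: dict | None = None) -> None:
    """Provenance record embedded with every output directory."""
    from . import __version__

    manifest: dict[str, Any] = {
        "package": "fallowcast",
        "version": __version__,
        "seed": int(seed),
        "config": config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
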