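"""Water-saving management scenarios evaluated per groundwater sub-basin.

Each scenario replaces part of the observed agricultural-ET distribution
with a counterfactual allocation and reports the fractional reduction in
total agricultural ET:

* crop switching — every pixel of a crop whose sub-basin mean exceeds the
  median crop's mean is re-assigned the median crop's mean;
* crop switching to the minimum — as above but targeting the lowest-mean
  crop (the theoretical ceiling for land-cover change);
* farming practices — pixels above their own crop's central consumption
  level are reduced to it (land cover unchanged);
* fallowing — the pixels above the sub-basin's 95th percentile are zeroed
  (taken out of production).

All four statistics are scale-free fractions of the baseline ET sum.
Negative agricultural-ET pixels are retained in the sums exactly as the
defining expressions state (an optional floor at zero exists for
sensitivity runs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("fallowcast")

SCENARIOS = ("crop_switching", "crop_switch_to_minimum", "farming_practice", "fallowing")


@dataclass
class ScenarioResult:
    """Fractional ET savings for one scenario in one sub-basin."""

    sub_basin_id: object
    scenario: str
    savings: float  # fraction of baseline agricultural ET; NaN if undefined
    n_pixels: int
    baseline_sum: float  # sum of et_ag over pixels (mm * pixels)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.savings)


def _result(sub_basin, scenario, numerator, et) -> ScenarioResult:
    denom = float(et.sum())
    if denom <= 0:
        logger.warning(
            "sub-basin %r: non-positive ET sum; %s savings undefined",
            sub_basin,
            scenario,
        )
        savings = np.nan
    else:
        savings = 1.0 - numerator / denom
    return ScenarioResult(
        sub_basin_id=sub_basin,
        scenario=scenario,
        savings=savings,
        n_pixels=len(et),
        baseline_sum=denom,
    )


def _crop_means(et: np.ndarray, crop: np.ndarray) -> pd.Series:
    return pd.Series(et).groupby(pd.Series(crop)).mean()


def crop_switching_savings(
    et: np.ndarray, crop: np.ndarray, sub_basin=None, target: str = "median"
) -> ScenarioResult:
    """Savings from switching high-ET crops to the median (or minimum) crop.

    With ET_c the mean agricultural ET of crop c in the sub-basin and M the
    median (resp. minimum) over the distinct crops' means, each pixel
    contributes min(ET_{c(i)}, M); savings = 1 - sum / sum(ET_i). The median
    is over crops (unweighted by area), with linear interpolation for even
    counts.
    """
    et = np.asarray(et, dtype=np.float64)
    crop = np.asarray(crop)
    means = _crop_means(et, crop)
    M = float(np.median(means.to_numpy())) if target == "median" else float(
        means.min()
    )
    per_pixel = means.reindex(crop).to_numpy()
    numerator = float(np.minimum(per_pixel, M).sum())
    name = "crop_switching" if target == "median" else "crop_switch_to_minimum"
    return _result(sub_basin, name, numerator, et)


def farming_practice_savings(
    et: np.ndarray, crop: np.ndarray, sub_basin=None, central: str = "median"
) -> ScenarioResult:
    """Savings from reducing high consumers to their crop's central level.

    T_c is the median (default) or mean agricultural ET of crop c in the
    sub-basin; each pixel contributes min(ET_i, T_{c(i)}).
    """
    et = np.asarray(et, dtype=np.float64)
    crop = np.asarray(crop)
    if central == "median":
        T = pd.Series(et).groupby(pd.Series(crop)).median()
    elif central == "mean":
        T = _crop_means(et, crop)
    else:
        raise ValueError(f"central must be 'median' or 'mean', got {central!r}")
    per_pixel = T.reindex(crop).to_numpy()
    numerator = float(np.minimum(et, per_pixel).sum())
    return _result(sub_basin, "farming_practice", numerator, et)


def fallowing_savings(
    et: np.ndarray, sub_basin=None, percentile: float = 95.0
) -> ScenarioResult:
    """Savings from fallowing the highest-ET tail of the sub-basin.

    q is the ``percentile`` quantile (linear interpolation) of agricultural
    ET; pixels strictly above q contribute zero, the rest contribute their
    own ET.
    """
    et = np.asarray(et, dtype=np.float64)
    q = float(np.percentile(et, percentile))
    numerator = float(np.where(et <= q, et, 0.0).sum())
    return _result(sub_basin, "fallowing", numerator, et)


def run_scenarios(
    annual: pd.DataFrame,
    value: str = "et_ag_ctrl_mm",
    crop_col: str = "land_cover",
    basin_col: str = "sub_basin",
    central: str = "median",
    fallow_percentile: float = 95.0,
    floor_at_zero: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate all four scenarios in every sub-basin and aggregate.

    ``annual`` must already be the scenario-ready table: a single year,
    orchard-filtered and covariate-adjusted (``value`` column). The region
    aggregate is ET-weighted — 1 - sum of numerators / sum of baselines over
    the defined sub-basins — not a mean of fractions; the unweighted mean is
    reported alongside. Returns (per-sub-basin table, aggregate table).
    """
    if annual["year"].nunique() > 1:
        raise ValueError("scenario analysis expects a single year of data")
    work = annual.dropna(subset=[value])
    results: list[ScenarioResult] = []
    for basin, sub in work.groupby(basin_col, sort=True):
        et = sub[value].to_numpy(dtype=np.float64)
        if floor_at_zero:
            et = np.clip(et, 0.0, None)
        crop = sub[crop_col].to_numpy()
        results.append(crop_switching_savings(et, crop, basin, target="median"))
        results.append(crop_switching_savings(et, crop, basin, target="minimum"))
        results.append(farming_practice_savings(et, crop, basin, central=central))
        results.append(fallowing_savings(et, basin, percentile=fallow_percentile))

    table = pd.DataFrame(
        [
            {
                "sub_basin_id": r.sub_basin_id,
                "scenario": r.scenario,
                "savings": r.savings,
                "n_pixels": r.n_pixels,
                "baseline_sum": r.baseline_sum,
            }
            for r in results
        ]
    )
    agg_rows = []
    for scenario in SCENARIOS:
        sub = table[(table["scenario"] == scenario) & table["savings"].notna()]
        n_undef = int((table["scenario"] == scenario).sum() - len(sub))
        denom = sub["baseline_sum"].sum()
        numer = ((1.0 - sub["savings"]) * sub["baseline_sum"]).sum()
        agg_rows.append(
            {
                "scenario": scenario,
                "savings_et_weighted": 1.0 - numer / denom if denom > 0 else np.nan,
                "savings_unweighted_mean": sub["savings"].mean(),
                "n_sub_basins": len(sub),
                "n_undefined": n_undef,
            }
        )
        if n_undef:
            logger.warning(
                "%d sub-basin(s) undefined for scenario %s", n_undef, scenario
            )
    return table, pd.DataFrame(agg_rows)
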