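"""County irrigation efficiency: the share of withdrawn water that becomes
agricultural ET.

Irrigation withdrawals and agricultural ET are compared in matching units
(mm/yr depth over irrigated land); their ratio is the irrigation efficiency.
All active agricultural land is treated as irrigated. Efficiency above 1 is
physically inconsistent (more consumption than withdrawal) and is flagged
rather than clipped — it signals a data problem worth surfacing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_geo import FALLOW
from .spatial_stats import group_mean_regression

logger = logging.getLogger("fallowcast")


def irrigation_depth(
    irrigation: pd.DataFrame,
    years=None,
    policy: str = "average",
) -> pd.DataFrame:
    """Per-county irrigation depth (mm/yr) from volume and area records.

    depth = volume / area, converted to mm (1 m^3 over 1 m^2 = 1000 mm).
    The default policy averages the per-year depths of the given years
    (reported irrigation census years rarely match the ET years); policy
    ``single-year`` uses exactly one year. Counties with zero irrigated
    area get a missing depth with a warning. An optional
    ``in_region_fraction`` column scales volumes for counties only partly
    inside the study region, assuming irrigation is evenly distributed over
    the county's irrigated land.
    """
    work = irrigation.copy()
    if years is not None:
        work = work[work["year"].isin(list(years))]
        if policy == "single-year" and len(set(years)) != 1:
            raise ValueError("single-year policy needs exactly one year")
    if len(work) == 0:
        raise ValueError("no irrigation records for the requested years")
    frac = work.get("in_region_fraction")
    volume = work["volume_m3"] * (frac if frac is not None else 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        depth = np.where(
            work["irrigated_area_m2"] > 0,
            volume / work["irrigated_area_m2"] * 1000.0,
            np.nan,
        )
    work = work.assign(depth_mm=depth)
    zero_area = work["irrigated_area_m2"] <= 0
    if zero_area.any():
        logger.warning(
            "%d county-year rows have zero irrigated area; depth missing",
            int(zero_area.sum()),
        )
    out = (
        work.groupby("county_id", as_index=False)
        .agg(
            irrigation_depth_mm=("depth_mm", "mean"),
            years_used=("year", lambda s: ",".join(str(v) for v in sorted(set(s)))),
        )
    )
    return out


def compute_efficiency(
    annual: pd.DataFrame,
    irrigation: pd.DataFrame,
    cluster_m: float = 75000.0,
    value: str = "et_ag_adj_mm",
    years=None,
) -> pd.DataFrame:
    """Per-county efficiency = mean agricultural-ET depth / irrigation depth.

    The county agricultural-ET depth is the cluster-robust group mean of
    year-adjusted agricultural ET over cropped pixels (all years pooled);
    its CI propagates to an efficiency CI by dividing through the
    irrigation depth. Counties absent from the irrigation table get a row
    with missing efficiency.
    """
    cropped = annual[annual["land_cover"] != FALLOW]
    est = group_mean_regression(cropped, by="county", cluster_m=cluster_m, value=value)
    est = est.rename(
        columns={
            "group": "county_id",
            "mean": "ag_et_depth_mm",
            "ci_low": "ag_et_ci_low",
            "ci_high": "ag_et_ci_high",
        }
    )
    depths = irrigation_depth(irrigation, years=years)
    out = est.merge(depths, on="county_id", how="left")
    missing = out["irrigation_depth_mm"].isna()
    if missing.any():
        logger.warning(
            "%d counties have no usable irrigation record", int(missing.sum())
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["efficiency"] = out["ag_et_depth_mm"] / out["irrigation_depth_mm"]
        out["efficiency_ci_low"] = out["ag_et_ci_low"] / out["irrigation_depth_mm"]
        out["efficiency_ci_high"] = out["ag_et_ci_high"] / out["irrigation_depth_mm"]
    out["flag_over_unity"] = out["efficiency"] > 1.0
    if out["flag_over_unity"].any():
        logger.warning(
            "efficiency > 1 for counties %s — inconsistent input data",
            out.loc[out["flag_over_unity"], "county_id"].tolist(),
        )
    return out[
        [
            "county_id",
            "ag_et_depth_mm",
            "ag_et_ci_low",
            "ag_et_ci_high",
            "irrigation_depth_mm",
            "efficiency",
            "efficiency_ci_low",
            "efficiency_ci_high",
            "flag_over_unity",
            "years_used",
            "n_pixels",
            "n_clusters",
        ]
    ]
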