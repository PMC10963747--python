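"""Agricultural ET: the observed-minus-counterfactual difference, annualized.

Agricultural ET is defined as total ET minus the naturally-occurring ET the
same land would exhibit if fallow. The difference is kept signed — negative
values are information about counterfactual error, not physical nonsense to
be clipped. Analysis runs on pixel-year sums with year-to-year level shifts
removed, so only spatial variation remains.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("fallowcast")

#: static per-pixel columns carried through annualization
_CARRY = [
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


def compute_ag_et(total, natural):
    """Signed difference total - natural (mm); missing operands propagate."""
    total = np.asarray(total, dtype=np.float64)
    natural = np.asarray(natural, dtype=np.float64)
    out = total - natural
    n_missing = int(np.sum(~np.isfinite(out)))
    if n_missing:
        logger.info("agricultural ET missing for %d entries", n_missing)
    return out


def annualize(
    pixel_months: pd.DataFrame,
    et_cols=("et_mm", "et_nat_mm"),
    strict: bool = True,
) -> pd.DataFrame:
    """Sum monthly values to pixel-years.

    Strict mode (default) excludes and logs pixel-years missing any month;
    with ``strict=False`` partial years are summed as-is. ``pet_mm`` is
    carried as the annual mean (the covariate used by the annual-scale
    regression adjustment). Adds ``et_ag_mm`` when both total and natural
    columns are present.
    """
    et_cols = [c for c in et_cols if c in pixel_months.columns]
    agg_spec = {c: (c, "sum") for c in et_cols}
    for c in _CARRY:
        if c in pixel_months.columns:
            agg_spec[c] = (c, "first")
    if "pet_mm" in pixel_months.columns:
        agg_spec["pet_mm"] = ("pet_mm", "mean")
    agg_spec["n_months"] = ("month", "nunique")

    complete_rows = pixel_months[[*et_cols]].notna().all(axis=1)
    n_na = int((~complete_rows).sum())
    if n_na:
        logger.info("dropping %d pixel-months with missing ET", n_na)
    annual = (
        pixel_months[complete_rows]
        .groupby(["pixel_id", "year"], as_index=False)
        .agg(**agg_spec)
    )
    if strict:
        incomplete = annual["n_months"] != 12
        if incomplete.any():
            logger.info(
                "excluding %d incomplete pixel-years (strict annualization)",
                int(incomplete.sum()),
            )
        annual = annual[~incomplete].reset_index(drop=True)
    annual = annual.drop(columns=["n_months"])
    if "et_mm" in annual.columns and "et_nat_mm" in annual.columns:
        annual["et_ag_mm"] = compute_ag_et(annual["et_mm"], annual["et_nat_mm"])
    return annual


def year_adjust(annual: pd.DataFrame, col: str = "et_ag_mm") -> pd.DataFrame:
    """Remove year-level shifts: value - (year mean - grand mean).

    After adjustment every year's mean equals the grand mean, while all
    within-year contrasts are untouched. A single-year input is returned
    unchanged (the scenario analysis, which uses one year only, relies on
    this fixed point).
    """
    if len(annual) == 0 or annual["year"].nunique() == 0:
        raise ValueError("year_adjust needs at least one year of data")
    out = annual.copy()
    adj_col = f"{col.removesuffix('_mm')}_adj_mm"
    if out["year"].nunique() == 1:
        # exact fixed point: with one year the year mean IS the grand mean
        out[adj_col] = out[col]
        return out
    grand = out[col].mean()
    year_means = out.groupby("year")[col].transform("mean")
    out[adj_col] = out[col] - (year_means - grand)
    return out


def filter_orchard_age(
    annual: pd.DataFrame,
    orchard_codes,
    max_young_years: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Drop orchards still establishing or about to be removed.

    Young orchards (bearing fruit for ``max_young_years`` or fewer years —
    the boundary age itself is removed) consume systematically less water,
    and orchards in their final production year are winding down; both
    would contaminate management-scenario baselines. Non-orchard crops pass
    through untouched; orchard rows lacking age attributes are retained
    with a warning.
    """
    is_orchard = annual["land_cover"].isin(list(orchard_codes))
    age = annual["orchard_age"]
    last = annual["orchard_last_year"]
    no_attrs = is_orchard & age.isna()
    n_warn = int(no_attrs.sum())
    if n_warn:
        logger.warning(
            "%d orchard rows lack age attributes; retained unfiltered", n_warn
        )
    young = is_orchard & (age <= max_young_years)
    final_year = is_orchard & (last == 1.0)
    drop = (young | final_year) & ~no_attrs
    report = {
        "n_orchard_rows": int(is_orchard.sum()),
        "n_young_removed": int((young & ~no_attrs).sum()),
        "n_last_year_removed": int((final_year & ~young & ~no_attrs).sum()),
        "n_missing_attrs_kept": n_warn,
    }
    return annual[~drop].reset_index(drop=True), report
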