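"""Naturally-occurring ET counterfactual learned from fallow land.

Fallow pixel-months are the only places where naturally-occurring ET is
directly observed; a gradient-boosted tree ensemble trained on them predicts
the ET every field would exhibit if left fallow. To keep nearby (and
therefore nearly identical) pixels out of multiple data splits, whole 2 km
square blocks are assigned to train/validation/test. Validation is scored on
annual (pixel-year) sums, matching the time step of all downstream analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, HistGradientBoostingRegressor
from sklearn.model_selection import KFold, ParameterSampler

from .io_geo import FALLOW, RunConfig

logger = logging.getLogger("fallowcast")

#: Predictors of naturally-occurring ET: position, time and the static
#: covariates (projected center coordinates stand in for lon/lat).
FEATURES = [
    "x",
    "y",
    "month",
    "year",
    "elevation",
    "aspect",
    "slope",
    "twi",
    "soil_quality",
    "pet_mm",
]
TARGET = "et_mm"


# ---------------------------------------------------------------------------
# Training-table assembly and cleaning
# ---------------------------------------------------------------------------

def assemble_training_table(pixels: pd.DataFrame) -> pd.DataFrame:
    """Fallow-only feature/target rows; incomplete rows dropped and counted."""
    if "land_cover" not in pixels.columns:
        raise ValueError("pixel table lacks land_cover labels")
    fallow = pixels[pixels["land_cover"] == FALLOW]
    if len(fallow) == 0:
        raise ValueError("no fallow pixel-months: counterfactual is untrainable")
    cols = ["pixel_id", *FEATURES, TARGET]
    missing_cols = [c for c in cols if c not in fallow.columns]
    if missing_cols:
        raise ValueError(f"pixel table lacks columns: {missing_cols}")
    table = fallow[cols]
    complete = table[[*FEATURES, TARGET]].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d fallow rows with missing feature/target", n_dropped)
    return table[complete].reset_index(drop=True)


def clean_fallow_outliers(
    table: pd.DataFrame,
    months: tuple = (7, 8, 9),
    percentile: float = 95.0,
) -> tuple[pd.DataFrame, dict]:
    """Drop pixel-years with implausibly high mid-summer ET.

    High July-September ET on a field labelled fallow suggests the label is
    wrong (the field was actively cropped). For each pixel-year with all of
    months 7-9 present, sum ET over those months; pixel-years whose sum is
    strictly above the ``percentile`` (linear-interpolation) of these sums
    are removed entirely. Pixel-years missing a summer month are exempt from
    the rule and counted in the report.
    """
    report = {
        "n_pixel_years": 0,
        "n_removed": 0,
        "n_exempt": 0,
        "threshold_mm": np.nan,
    }
    if len(table) == 0:
        return table, report
    summer = table[table["month"].isin(months)]
    counts = summer.groupby(["pixel_id", "year"])["month"].nunique()
    complete = counts[counts == len(months)].index
    report["n_exempt"] = int(
        len(table.groupby(["pixel_id", "year"]).size()) - len(complete)
    )
    if report["n_exempt"]:
        logger.info(
            "%d pixel-years lack a complete Jul-Sep record; exempt from cleaning",
            report["n_exempt"],
        )
    sums = summer.groupby(["pixel_id", "year"])[TARGET].sum()[counts == len(months)]
    report["n_pixel_years"] = int(len(sums))
    if len(sums) == 0:
        return table, report
    threshold = float(np.percentile(sums.to_numpy(), percentile))
    report["threshold_mm"] = threshold
    bad = set(sums[sums > threshold].index)
    report["n_removed"] = len(bad)
    keys = pd.MultiIndex.from_frame(table[["pixel_id", "year"]])
    kept = table[~keys.isin(bad)].reset_index(drop=True)
    return kept, report


# ---------------------------------------------------------------------------
# Spatially blocked splitting
# ---------------------------------------------------------------------------

@dataclass
class BlockSplit:
    """Assignment of square spatial blocks to train/validation/test."""

    block_m: float
    assignment: pd.Series  # block_id -> partition name
    fractions: dict  # partition -> realized block-count fraction

    def partition_of(self, block_ids) -> pd.Series:
        return pd.Series(np.asarray(block_ids)).map(self.assignment)


def block_id(x, y, block_m: float) -> np.ndarray:
    """Square-tile identifier anchored at the coordinate origin."""
    bx = np.floor(np.asarray(x) / block_m).astype(np.int64)
    by = np.floor(np.asarray(y) / block_m).astype(np.int64)
    # collision-free pairing on a signed lattice
    return (bx + 2**20) * 2**22 + (by + 2**20)


def allocate_blocks(block_ids, fractions, seed) -> pd.Series:
    """Randomly assign whole blocks to partitions at the given fractions.

    Counts per partition follow the largest-remainder rule, so 8180 blocks
    at (0.6, 0.1, 0.3) give exactly 4908 / 818 / 2454.
    """
    names = ("train", "validation", "test")
    ids = np.unique(np.asarray(block_ids))
    n = len(ids)
    fr = np.asarray(fractions, dtype=float)
    base = np.floor(fr * n).astype(int)
    rem = fr * n - base
    for i in np.argsort(-rem)[: n - base.sum()]:
        base[i] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    labels = np.repeat(names, base)
    return pd.Series(labels, index=perm, name="partition").sort_index()


def block_split(
    table: pd.DataFrame,
    block_m: float = 2000.0,
    fractions=(0.6, 0.1, 0.3),
    seed: int = 0,
) -> BlockSplit:
    """Partition a pixel table by whole spatial blocks (no leakage).

    Blocks are squares of side ``block_m`` (default 2000 m, i.e. 2 km
    tiles); every pixel of a block lands in the same partition.
    """
    fr = np.asarray(fractions, dtype=float)
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    ids = block_id(table["x"].to_numpy(), table["y"].to_numpy(), block_m)
    uniq = np.unique(ids)
    if len(uniq) < 3:
        raise ValueError(
            f"only {len(uniq)} non-empty blocks; need at least 3 to split"
        )
    assignment = allocate_blocks(uniq, fr, seed)
    counts = assignment.value_counts()
    fractions_realized = {
        name: float(counts.get(name, 0)) / len(uniq)
        for name in ("train", "validation", "test")
    }
    return BlockSplit(
        block_m=block_m, assignment=assignment, fractions=fractions_realized
    )


def apply_split(table: pd.DataFrame, split: BlockSplit) -> pd.DataFrame:
    """Attach block and partition columns to a pixel table."""
    out = table.copy()
    ids = block_id(out["x"].to_numpy(), out["y"].to_numpy(), split.block_m)
    out["block"] = ids
    out["partition"] = split.assignment.reindex(ids).to_numpy()
    return out


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class CounterfactualModel:
    """A fitted boosted-tree predictor of naturally-occurring ET (mm/month)."""

    estimator: object
    features: list
    params: dict
    backend: str
    seed: int
    n_train: int
    min_samples_split: int
    min_samples_leaf: int
    search_results: pd.DataFrame = field(repr=False, default=None)

    def predict(self, pixels: pd.DataFrame) -> np.ndarray:
        """Predicted natural ET, clipped below at zero (a depth cannot be
        negative), for every requested pixel-month, cropped or fallow."""
        missing = [f for f in self.features if f not in pixels.columns]
        if missing:
            raise ValueError(f"missing model feature(s): {missing}")
        X = pixels[self.features].to_numpy(dtype=np.float64)
        return np.clip(self.estimator.predict(X), 0.0, None)


def _scaled_min_samples(config: RunConfig, n_train: int) -> tuple[int, int]:
    """The minimum-samples constraints (200 to split, 100 per leaf) are
    calibrated to a reference training size; smaller training sets get
    proportionally smaller minima."""
    scale = min(1.0, n_train / config.reference_train_size)
    mss = max(2, int(round(config.min_samples_split * scale)))
    msl = max(1, int(round(config.min_samples_leaf * scale)))
    return mss, msl


def _make_estimator(backend, params, mss, msl, seed):
    if backend == "hist":
        return HistGradientBoostingRegressor(
            min_samples_leaf=msl,
            early_stopping=False,
            random_state=seed,
            **params,
        )
    if backend == "classic":
        p = dict(params)
        if "max_iter" in p:
            p["n_estimators"] = p.pop("max_iter")
        return GradientBoostingRegressor(
            min_samples_split=mss,
            min_samples_leaf=msl,
            random_state=seed,
            **p,
        )
    raise ValueError(f"unknown model backend: {backend!r}")


def fit_counterfactual(
    train: pd.DataFrame,
    validation: pd.DataFrame | None,
    config: RunConfig,
    seed: int | None = None,
) -> CounterfactualModel:
    """Tune and fit the boosted ensemble on fallow training rows.

    Hyperparameters are chosen by randomized search (``n_search_candidates``
    draws from ``config.search_space``) scored by k-fold CV mean R^2 on an
    unclustered subsample of the training partition; the winning candidate
    is refit on the full training partition. All randomness is seeded.
    """
    if not config.search_space:
        raise ValueError("hyperparameter search space is empty")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7001]))
    n_train = len(train)
    mss, msl = _scaled_min_samples(config, n_train)

    X = train[FEATURES].to_numpy(dtype=np.float64)
    y = train[TARGET].to_numpy(dtype=np.float64)

    n_sub = min(config.search_subsample, n_train)
    sub_idx = rng.choice(n_train, size=n_sub, replace=False)
    Xs, ys = X[sub_idx], y[sub_idx]

    sampler = ParameterSampler(
        config.search_space,
        n_iter=config.n_search_candidates,
        random_state=int(rng.integers(2**31 - 1)),
    )
    cv = KFold(
        n_splits=config.search_cv_folds,
        shuffle=True,
        random_state=int(rng.integers(2**31 - 1)),
    )
    est_seed = int(rng.integers(2**31 - 1))

    records = []
    best_score, best_params = -np.inf, None
    for params in sampler:
        scores = []
        for tr, te in cv.split(Xs):
            est = _make_estimator(config.model_backend, params, mss, msl, est_seed)
            est.fit(Xs[tr], ys[tr])
            scores.append(est.score(Xs[te], ys[te]))
        mean_score = float(np.mean(scores))
        records.append({**params, "cv_r2": mean_score})
        if mean_score > best_score:
            best_score, best_params = mean_score, params
    logger.info("best CV R2 %.4f with %s", best_score, best_params)

    final = _make_estimator(config.model_backend, best_params, mss, msl, est_seed)
    final.fit(X, y)
    model = CounterfactualModel(
        estimator=final,
        features=list(FEATURES),
        params=dict(best_params),
        backend=config.model_backend,
        seed=seed,
        n_train=n_train,
        min_samples_split=mss,
        min_samples_leaf=msl,
        search_results=pd.DataFrame(records),
    )
    if validation is not None and len(validation):
        r2 = final.score(
            validation[FEATURES].to_numpy(dtype=np.float64),
            validation[TARGET].to_numpy(dtype=np.float64),
        )
        logger.info("validation-partition monthly R2 %.4f", r2)
    return model


def predict_natural_et(model: CounterfactualModel, pixels: pd.DataFrame) -> np.ndarray:
    """Counterfactual natural ET (mm/month) for arbitrary pixel-months."""
    return model.predict(pixels)


# ---------------------------------------------------------------------------
# Annual validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    r2: float
    mae_mm: float
    n_pixel_years: int
    n_excluded: int
    by_year: pd.DataFrame
    by_block: pd.DataFrame


def validate_annual(
    model: CounterfactualModel,
    test: pd.DataFrame,
    block_m: float = 2000.0,
) -> ValidationReport:
    """Score the model on pixel-year sums of held-out fallow land.

    All downstream analysis runs on annual ET, so skill is reported at the
    annual scale: predictions and observations are summed to pixel-years
    (incomplete pixel-years are excluded and counted), then R^2 and MAE are
    computed, along with mean residuals by spatial block and by year to
    reveal structured error.
    """
    work = test.copy()
    work["pred"] = model.predict(work)
    grouped = work.groupby(["pixel_id", "year"])
    n_months = grouped["month"].nunique()
    complete = n_months[n_months == 12].index
    n_excluded = int(len(n_months) - len(complete))
    if n_excluded:
        logger.info("excluded %d incomplete pixel-years from validation", n_excluded)
    agg = grouped.agg(
        obs=(TARGET, "sum"),
        pred=("pred", "sum"),
        x=("x", "first"),
        y=("y", "first"),
    )
    agg = agg.loc[agg.index.isin(complete)]
    obs = agg["obs"].to_numpy()
    pred = agg["pred"].to_numpy()
    resid = obs - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    mae = float(np.mean(np.abs(resid)))
    agg = agg.assign(resid=resid)
    agg["block"] = block_id(agg["x"].to_numpy(), agg["y"].to_numpy(), block_m)
    by_block = (
        agg.groupby("block")["resid"].agg(["mean", "count"]).reset_index()
    )
    by_year = (
        agg.reset_index().groupby("year")["resid"].agg(["mean", "count"]).reset_index()
    )
    return ValidationReport(
        r2=r2,
        mae_mm=mae,
        n_pixel_years=len(agg),
        n_excluded=n_excluded,
        by_year=by_year,
        by_block=by_block,
    )
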