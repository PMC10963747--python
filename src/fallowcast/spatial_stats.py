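"""Group-mean inference with spatially clustered standard errors.

Agricultural ET is strongly spatially autocorrelated (whole fields share one
management regime), so iid standard errors on group means would be far too
small. Following common practice in spatial econometrics, errors are allowed
to correlate arbitrarily within square tiles (clusters); the cluster size is
chosen from an empirical variogram of the residual autocorrelation (75 km on
continental-scale data; proportionally smaller on the synthetic region).

The group-mean "regression" is a saturated dummy regression, whose point
estimates are exactly the per-group arithmetic means; the cluster-robust
sandwich then reduces to a per-group sum over squared within-cluster
residual totals, with a G/(G-1) finite-cluster correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

logger = logging.getLogger("fallowcast")

Z95 = 1.96  # large-cluster normal approximation for 95% intervals

COVARIATES = ["pet_mm", "soil_quality", "twi", "elevation", "aspect", "slope"]


def cluster_id(x, y, cluster_m: float) -> np.ndarray:
    """Square-tile cluster label anchored at the coordinate origin."""
    cx = np.floor(np.asarray(x) / cluster_m).astype(np.int64)
    cy = np.floor(np.asarray(y) / cluster_m).astype(np.int64)
    return (cx + 2**20) * 2**22 + (cy + 2**20)


def group_mean_regression(
    annual: pd.DataFrame,
    by: str | None = None,
    cluster_m: float = 75000.0,
    value: str = "et_ag_adj_mm",
) -> pd.DataFrame:
    """Per-group means of ``value`` with cluster-robust 95% CIs.

    ``by=None`` gives the overall mean (a single group). For each group g
    with mean m_g and residuals e_i, the sandwich variance is

        SE_g^2 = G/(G-1) * sum_c (sum_{i in c} e_i)^2 / n_g^2

    over the G clusters intersecting the group. A group contained in a
    single cluster gets a missing SE with a warning.
    """
    if cluster_m <= 0:
        raise ValueError("cluster_m must be > 0")
    work = annual[[value, "x", "y"]].copy()
    if by is None:
        work["_group"] = "all"
        by = "_group"
    else:
        if by not in annual.columns:
            raise ValueError(f"grouping column {by!r} not present")
        work["_group"] = annual[by]
    work = work.dropna(subset=[value])
    work["_cluster"] = cluster_id(
        work["x"].to_numpy(), work["y"].to_numpy(), cluster_m
    )

    rows = []
    for group, sub in work.groupby("_group", sort=True):
        vals = sub[value].to_numpy(dtype=np.float64)
        n = len(vals)
        mean = float(vals.mean())
        cl_sums = pd.Series(vals - mean).groupby(sub["_cluster"].to_numpy()).sum()
        G = len(cl_sums)
        if G < 2:
            logger.warning(
                "group %r spans a single spatial cluster; SE not identified", group
            )
            se = np.nan
        else:
            se = float(np.sqrt(G / (G - 1) * np.sum(cl_sums.to_numpy() ** 2)) / n)
        rows.append(
            {
                "group": group,
                "mean": mean,
                "se": se,
                "ci_low": mean - Z95 * se if np.isfinite(se) else np.nan,
                "ci_high": mean + Z95 * se if np.isfinite(se) else np.nan,
                "n_pixels": n,
                "n_clusters": G,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Least-squares helpers (variance decomposition and covariate control)
# ---------------------------------------------------------------------------

def _design_matrix(
    annual: pd.DataFrame,
    grouping: str | None,
    covariates,
    aspect_circular: bool,
) -> tuple[np.ndarray, list]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    if grouping is not None:
        dummies = pd.get_dummies(annual[grouping], prefix=str(grouping))
        cols.extend(dummies.to_numpy(dtype=np.float64).T)
        names.extend(dummies.columns)
    for cov in covariates or []:
        v = annual[cov].to_numpy(dtype=np.float64)
        if cov == "aspect" and aspect_circular:
            rad = np.deg2rad(v)
            cols.extend([np.sin(rad), np.cos(rad)])
            names.extend(["aspect_sin", "aspect_cos"])
        else:
            cols.append(v)
            names.append(cov)
    if not cols:
        raise ValueError("no regressors given")
    return np.column_stack(cols), names


def variance_explained(
    annual: pd.DataFrame,
    grouping: str | None = None,
    covariates=None,
    value: str = "et_ag_adj_mm",
    aspect_circular: bool = True,
) -> float:
    """R^2 of the least-squares fit of ``value`` on dummies and/or covariates.

    The R^2 of a regression is the fraction of variance the regressor set
    explains — e.g. how much of the spread in agricultural ET is due to crop
    choice. Collinear columns are harmless (minimum-norm solution; R^2 is
    unaffected) but are reported.
    """
    X, names = _design_matrix(annual, grouping, covariates, aspect_circular)
    keep = np.isfinite(X).all(axis=1) & annual[value].notna().to_numpy()
    X = X[keep]
    y = annual.loc[keep, value].to_numpy(dtype=np.float64)
    X1 = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(X1)
    if rank < X1.shape[1]:
        logger.warning(
            "design matrix is rank deficient (%d < %d); collinear regressors "
            "dropped implicitly",
            rank,
            X1.shape[1],
        )
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def covariate_adjust(
    annual: pd.DataFrame,
    covariates=COVARIATES,
    value: str = "et_ag_adj_mm",
    out_col: str = "et_ag_ctrl_mm",
    aspect_circular: bool = True,
) -> pd.DataFrame:
    """Control for climate, soils and topography by linear regression.

    Each pixel's value is moved to what it would be at sample-average
    covariates: residual + grand mean. The grand mean is preserved exactly;
    rows with missing covariates are dropped and logged. Aspect, a circular
    quantity in degrees, enters as its sine and cosine by default (a
    raw-degrees option is kept for literal replication).
    """
    X, _ = _design_matrix(annual, None, covariates, aspect_circular)
    keep = np.isfinite(X).all(axis=1) & annual[value].notna().to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("covariate_adjust: dropped %d rows with missing values", n_drop)
    out = annual[keep].reset_index(drop=True)
    Xk = X[keep]
    y = out[value].to_numpy(dtype=np.float64)
    X1 = np.column_stack([np.ones(len(Xk)), Xk])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    out[out_col] = resid + y.mean()
    return out


# ---------------------------------------------------------------------------
# Empirical variogram
# ---------------------------------------------------------------------------

def empirical_variogram(
    annual: pd.DataFrame,
    value: str = "et_ag_adj_mm",
    max_lag_m: float = 10000.0,
    n_bins: int = 20,
    max_pairs: int = 500_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Semivariance gamma(h) = mean squared difference / 2, binned by distance.

    Used to diagnose the range of spatial autocorrelation and hence choose
    the cluster size for robust inference. All pairs are enumerated when
    feasible; otherwise random pairs are sampled up to ``max_pairs``.
    Returns columns lag_m (bin centers), semivariance, n_pairs; empty bins
    get missing semivariance.
    """
    if max_lag_m <= 0:
        raise ValueError("max_lag_m must be > 0")
    sub = annual.dropna(subset=[value])
    n = len(sub)
    if n < 2:
        raise ValueError("need at least two pixels for a variogram")
    xy = sub[["x", "y"]].to_numpy(dtype=np.float64)
    vals = sub[value].to_numpy(dtype=np.float64)
    if n * (n - 1) // 2 <= max_pairs:
        d = pdist(xy)
        dv2 = pdist(vals[:, None], metric="sqeuclidean")
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=max_pairs)
        j = rng.integers(0, n, size=max_pairs)
        ok = i != j
        i, j = i[ok], j[ok]
        d = np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1])
        dv2 = (vals[i] - vals[j]) ** 2
    edges = np.linspace(0.0, max_lag_m, n_bins + 1)
    which = np.digitize(d, edges) - 1
    inside = (which >= 0) & (which < n_bins)
    which, dv2 = which[inside], dv2[inside]
    gamma = np.full(n_bins, np.nan)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=dv2, minlength=n_bins)
    nonzero = counts > 0
    gamma[nonzero] = sums[nonzero] / counts[nonzero] / 2.0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame(
        {"lag_m": centers, "semivariance": gamma, "n_pairs": counts}
    )
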