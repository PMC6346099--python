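"""Microarray-style quality filtering, imputation and normalization.

The default pipeline order is filter -> impute -> normalize: pixel-coverage
filtering marks low-quality probe measurements missing, k-nearest-neighbour
imputation fills them from the most similar features, and quantile
normalization equalizes between-array intensity distributions.  Both orders
(impute-then-normalize and normalize-then-impute) are exposed because the
right choice depends on how missingness arose on a given platform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import median_filter

PROBE_COLUMNS = ("probe_id", "subject_id", "intensity", "pixel_fraction")


def filter_probes_by_pixels(
    probes: pd.DataFrame, min_fraction: float = 0.75
) -> pd.DataFrame:
    """Mark probe intensities missing when pixel coverage is below threshold.

    ``probes`` is long-format with columns probe_id, subject_id, intensity,
    pixel_fraction (the observed fraction of the maximum possible pixel
    count).  A probe is retained when its fraction is **at least**
    ``min_fraction``; the default 0.75 keeps probes with 75% coverage
    exactly.  Returns a probes x subjects matrix with NaN where filtered.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0, 1]")
    if len(probes) == 0:
        raise ValueError("empty probe table")
    missing_cols = set(PROBE_COLUMNS) - set(probes.columns)
    if missing_cols:
        raise ValueError(f"probe table lacks columns {sorted(missing_cols)}")
    frac = probes["pixel_fraction"].to_numpy(float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("pixel_fraction must lie in [0, 1]")
    values = probes["intensity"].where(frac >= min_fraction)
    long = probes.assign(intensity=values)
    wide = long.pivot(index="probe_id", columns="subject_id", values="intensity")
    # preserve first-appearance order rather than lexical order
    return wide.reindex(
        index=pd.unique(probes["probe_id"]), columns=pd.unique(probes["subject_id"])
    )


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Between-array quantile normalization (features x subjects).

    Every column is mapped onto the common distribution formed by the
    row-means of the column-sorted input, preserving within-column ranks.
    Ties receive the average of the values at the tied positions.  Missing
    values are not allowed: impute first (see knn_impute).
    """
    X = matrix.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; run knn_impute first")
    if X.size == 0:
        raise ValueError("empty matrix")
    n = X.shape[0]
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    ranks = stats.rankdata(X, method="average", axis=0)  # 1..n, half-ranks on ties
    out = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def knn_impute(matrix: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Impute missing entries from the k nearest features.

    Distances are Euclidean over pairwise-complete positions on mean-centered
    features, rescaled by sqrt(p / p_obs) to be comparable across different
    amounts of overlap.  A missing entry becomes the unweighted mean of the
    values of the k nearest features observed at that position (fewer if
    fewer are available).  Observed entries are never altered.
    """
    if int(k) != k or k < 1:
        raise ValueError("k must be a positive integer")
    k = int(k)
    X = matrix.to_numpy(float)
    obs = ~np.isnan(X)
    dead = ~obs.any(axis=1)
    if dead.any():
        names = list(matrix.index[dead])
        raise ValueError(f"features entirely missing: {names}")
    if not np.isnan(X).any():
        return matrix.copy()

    t, p = X.shape
    centers = np.nanmean(X, axis=1)
    C = np.where(obs, X - centers[:, None], 0.0)
    M = obs.astype(float)
    sq = C**2
    # sum over co-observed positions of (c_i - c_j)^2, via three products
    S = sq @ M.T + M @ sq.T - 2.0 * C @ C.T
    p_obs = M @ M.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(p_obs > 0, (p / p_obs) * S, np.inf)
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 0.0)

    out = X.copy()
    rows_with_missing = np.where(~obs.all(axis=1))[0]
    for i in rows_with_missing:
        order = np.argsort(d2[i], kind="stable")
        for j in np.where(~obs[i])[0]:
            donors = order[obs[order, j] & np.isfinite(d2[i, order])]
            if donors.size == 0:
                raise ValueError(
                    f"no neighbour observed at position {matrix.columns[j]!r} "
                    f"for feature {matrix.index[i]!r}"
                )
            out[i, j] = X[donors[:k], j].mean()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def remove_intensity_trend(matrix: pd.DataFrame, window: int = 101) -> pd.DataFrame:
    """Optional within-array intensity-trend correction (defaults off in the
    pipeline): subtracts a running median over features ordered by average
    intensity, re-adding each array's median level.  A single-channel
    stand-in for dye/intensity trend smoothing; no-op-like when arrays share
    a common intensity profile."""
    X = matrix.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    order = np.argsort(X.mean(axis=1), kind="stable")
    out = X.copy()
    for j in range(X.shape[1]):
        col = X[order, j]
        trend = median_filter(col, size=min(window, len(col)), mode="nearest")
        out[order, j] = col - trend + np.median(X[:, j])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def preprocess_pipeline(
    probes: pd.DataFrame,
    min_fraction: float = 0.75,
    k: int = 15,
    order: tuple[str, ...] = ("filter", "impute", "normalize"),
    detrend: bool = False,
) -> pd.DataFrame:
    """Run the configured preprocessing stages; default filter, impute,
    normalize."""
    allowed = {"filter", "impute", "normalize"}
    if set(order) - allowed or order[0] != "filter":
        raise ValueError("order must start with 'filter' and use only "
                         f"{sorted(allowed)}")
    matrix = filter_probes_by_pixels(probes, min_fraction)
    for stage in order[1:]:
        if stage == "impute":
            matrix = knn_impute(matrix, k)
        elif stage == "normalize":
            matrix = quantile_normalize(matrix)
    if detrend:
        matrix = remove_intensity_trend(matrix)
    return matrix
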