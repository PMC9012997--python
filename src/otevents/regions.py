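"""Ward regionalization of stations into o-t-regions.

Stations are clustered on their joint standardized daily TX and MDA8O3
series so that regions group stations with similar day-to-day ozone and
temperature variability.  Agglomerative clustering with the Ward variance
criterion is used; the cluster count is chosen by the elbow of the merge
heights (subject to a minimum of four regions), and per-region
representative stations of each background type are the stations nearest
their region centroid in feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass
class FeatureMatrix:
    station_ids: list[str]
    X: np.ndarray  # (n_stations, 2 * n_season_days)
    imputation_log: pd.DataFrame


@dataclass
class ClusterSolution:
    linkage: np.ndarray  # scipy linkage matrix
    k: int
    labels: np.ndarray  # 1..k per station
    station_ids: list[str]
    centroids: np.ndarray  # (k, n_features)
    X: np.ndarray = field(repr=False, default=None)


@dataclass
class Representative:
    region: int
    rank: int
    station_id: str
    station_type: str
    distance: float


def impute_daily_means(
    wide: pd.DataFrame, *, mode: str = "network"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing values with daily means.

    Parameters
    ----------
    wide
        One variable, dates x stations (DatetimeIndex, one column per
        station id).
    mode
        ``"network"`` (default): a missing value on date d is replaced by
        the cross-station mean of that date, preserving the synoptic
        day-to-day signal.  ``"calendar"``: per-station mean of the same
        calendar day across years.

    Returns the completed frame and a log with one row per imputed cell.
    """
    out = wide.copy()
    log_rows = []
    if mode == "network":
        row_means = wide.mean(axis=1, skipna=True)
        if wide.notna().sum(axis=1).min() == 0:
            bad = wide.index[wide.notna().sum(axis=1) == 0][0]
            raise ValueError(f"all stations missing on {bad.date()}")
        for col in wide.columns:
            miss = wide[col].isna()
            out.loc[miss, col] = row_means[miss]
            for d in wide.index[miss]:
                log_rows.append({"station_id": col, "date": d, "value": row_means[d]})
    elif mode == "calendar":
        doy = wide.index.strftime("%m-%d")
        for col in wide.columns:
            means = wide[col].groupby(doy).transform("mean")
            miss = wide[col].isna()
            out.loc[miss, col] = means[miss]
            for d in wide.index[miss]:
                log_rows.append({"station_id": col, "date": d, "value": out.loc[d, col]})
        if out.isna().any().any():
            raise ValueError("calendar-day means leave missing values")
    else:
        raise ValueError(f"unknown imputation mode: {mode!r}")
    log = pd.DataFrame(log_rows, columns=["station_id", "date", "value"])
    return out, log


def _standardize_rows(block: np.ndarray, ids) -> np.ndarray:
    mu = block.mean(axis=1, keepdims=True)
    sd = block.std(axis=1, ddof=0, keepdims=True)
    zero = np.isclose(sd[:, 0], 0.0)
    if zero.any():
        bad = [ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero-variance series for station(s): {bad}")
    return (block - mu) / sd


def build_feature_matrix(
    tx_wide: pd.DataFrame, o3_wide: pd.DataFrame, *, imputation_log=None
) -> FeatureMatrix:
    """Concatenate per-station standardized TX and MDA8O3 blocks.

    Inputs are completed (no missing values) dates x stations frames over
    the base-period season; each variable block is standardized per
    station (mean 0, sd 1) before concatenation, so the feature dimension
    is twice the number of season days.
    """
    if list(tx_wide.columns) != list(o3_wide.columns):
        raise ValueError("TX and MDA8O3 frames must share station columns")
    if tx_wide.isna().any().any() or o3_wide.isna().any().any():
        raise ValueError("feature matrix requires completed series")
    ids = list(tx_wide.columns)
    tx = _standardize_rows(tx_wide.to_numpy(dtype=float).T, ids)
    o3 = _standardize_rows(o3_wide.to_numpy(dtype=float).T, ids)
    X = np.hstack([tx, o3])
    if imputation_log is None:
        imputation_log = pd.DataFrame(columns=["station_id", "date", "value"])
    return FeatureMatrix(ids, X, imputation_log)


def ward_cluster(matrix: FeatureMatrix, k: int) -> ClusterSolution:
    """Agglomerative clustering with the Ward variance-minimization criterion."""
    ids = matrix.station_ids
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate station ids")
    n = len(ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} invalid for {n} stations")
    Z = linkage(matrix.X, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    centroids = np.vstack(
        [matrix.X[labels == c].mean(axis=0) for c in range(1, labels.max() + 1)]
    )
    return ClusterSolution(Z, int(labels.max()), labels, ids, centroids, matrix.X)


def select_k(
    Z: np.ndarray, *, k_min: int = 4, k_max: int | None = None,
    dominance_ratio: float = 1.5,
) -> int:
    """Choose the cluster count at the elbow of the Ward merge heights.

    The elbow is the k in [k_min, k_max] with the largest drop in merge
    height between successive merges: cutting the dendrogram at k clusters
    is supported when the merge that would reduce k to k-1 sits far above
    the previous one.  If the winning gap does not exceed
    ``dominance_ratio`` times the median candidate gap (featureless data),
    k_min is returned.
    """
    n = Z.shape[0] + 1
    if k_max is None:
        k_max = min(n - 1, 10)
    if k_max < k_min:
        raise ValueError(f"k_max={k_max} < k_min={k_min}")
    k_max = min(k_max, n - 1)
    heights = Z[:, 2]
    gaps = {}
    for k in range(k_min, k_max + 1):
        # with k clusters, the next merge has height heights[n-k];
        # the previous one heights[n-k-1]
        gaps[k] = heights[n - k] - heights[n - k - 1]
    best_k = max(gaps, key=lambda k: (gaps[k], -k))
    med = float(np.median(list(gaps.values())))
    if med > 0 and gaps[best_k] < dominance_ratio * med:
        return k_min
    return best_k


def assign_new_station(x: np.ndarray, solution: ClusterSolution) -> int:
    """Assign a feature vector to the region of minimal Ward distance.

    The Ward distance increase of adding x to cluster c of size n_c is
    n_c/(n_c+1) * ||x - centroid_c||^2; ties go to the smaller label.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (solution.centroids.shape[1],):
        raise ValueError("feature-vector dimension mismatch")
    sizes = np.array(
        [(solution.labels == c).sum() for c in range(1, solution.k + 1)], dtype=float
    )
    d2 = ((solution.centroids - x) ** 2).sum(axis=1)
    ward = sizes / (sizes + 1.0) * d2
    return int(np.argmin(ward)) + 1


def representative_stations(
    solution: ClusterSolution, metadata: pd.DataFrame
) -> list[Representative]:
    """Per region, the station of each background type nearest the centroid.

    ``metadata`` maps ``station_id`` to ``station_type``.  Within a region,
    representatives are ranked 1, 2, 3 by Euclidean distance to the region
    centroid across the types present (first = closest).
    """
    types = metadata.set_index("station_id")["station_type"]
    reps: list[Representative] = []
    for c in range(1, solution.k + 1):
        members = np.flatnonzero(solution.labels == c)
        if len(members) == 0:
            raise RuntimeError(f"region {c} is empty")
        centroid = solution.centroids[c - 1]
        chosen = {}
        for i in members:
            sid = solution.station_ids[i]
            st = types[sid]
            d = float(np.linalg.norm(solution.X[i] - centroid))
            if st not in chosen or d < chosen[st][0]:
                chosen[st] = (d, sid)
        ranked = sorted((d, sid, st) for st, (d, sid) in chosen.items())
        for rank, (d, sid, st) in enumerate(ranked, start=1):
            reps.append(Representative(c, rank, sid, st, d))
    return reps
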