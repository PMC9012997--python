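"""Station-based predictor series from gridded fields, and ESM preparation.

Meteorological predictors (850-hPa geopotential height GH, specific
humidity SH and mean temperature MT, plus surface solar radiation SSRD)
are extracted per station as the mean of the nine grid boxes around the
station's grid cell, then standardized.  Earth-system-model output is
regridded bilinearly to the reference grid, bias-corrected by monthly
linear scaling against the reference (additive monthly mean offsets),
and merged-standardized (historical + scenario concatenated) before
entering projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

PREDICTOR_VARS = ("GH", "SH", "MT", "SSRD")


@dataclass
class Standardization:
    mean: float
    sd: float

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def extract_station_series(field: xr.DataArray, lat: float, lon: float) -> pd.Series:
    """Nine-grid-box mean around the station, per day.

    ``field`` has dims (time, lat, lon).  The station's cell is the grid
    point nearest its coordinates; the 3x3 neighborhood is clipped at the
    domain edges, the mean running over the available cells.
    """
    lats = np.asarray(field["lat"].values, dtype=float)
    lons = np.asarray(field["lon"].values, dtype=float)
    half_lat = np.median(np.abs(np.diff(lats))) / 2 if len(lats) > 1 else 0.5
    half_lon = np.median(np.abs(np.diff(lons))) / 2 if len(lons) > 1 else 0.5
    if not (lats.min() - half_lat <= lat <= lats.max() + half_lat):
        raise ValueError(f"station latitude {lat} outside grid")
    if not (lons.min() - half_lon <= lon <= lons.max() + half_lon):
        raise ValueError(f"station longitude {lon} outside grid")
    i = int(np.argmin(np.abs(lats - lat)))
    j = int(np.argmin(np.abs(lons - lon)))
    ii = slice(max(i - 1, 0), min(i + 2, len(lats)))
    jj = slice(max(j - 1, 0), min(j + 2, len(lons)))
    block = field.isel(lat=ii, lon=jj).mean(dim=("lat", "lon"))
    return pd.Series(block.values, index=pd.to_datetime(field["time"].values))


def standardize_series(
    series: pd.Series, reference: pd.Series | None = None
) -> tuple[pd.Series, Standardization]:
    """Standardize a predictor series with parameters from ``reference``.

    With no reference the series is its own reference.  Zero reference
    variance raises.
    """
    ref = series if reference is None else reference
    mu = float(ref.mean())
    sd = float(ref.std(ddof=0))
    if np.isclose(sd, 0.0):
        raise ValueError("zero standard deviation over the reference period")
    params = Standardization(mu, sd)
    return pd.Series(params.transform(series.to_numpy()), index=series.index), params


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired values")
    if np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
        raise ValueError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(x[ok], y[ok]).statistic)


def agreement_check(
    series_by_station: dict[str, pd.Series], *, min_rho: float = 0.5
) -> pd.DataFrame:
    """Pairwise Spearman agreement of one predictor across a region's stations.

    Returns one row per unordered station pair with the correlation and a
    flag for pairs below ``min_rho`` (the within-region homogeneity level
    expected of a well-formed o-t-region).
    """
    ids = sorted(series_by_station)
    rows = []
    for a_i, a in enumerate(ids):
        for b in ids[a_i + 1:]:
            joined = pd.concat(
                [series_by_station[a], series_by_station[b]], axis=1, join="inner"
            ).dropna()
            rho = spearman(joined.iloc[:, 0], joined.iloc[:, 1])
            rows.append(
                {"station_a": a, "station_b": b, "rho": rho, "flagged": rho < min_rho}
            )
    return pd.DataFrame(rows, columns=["station_a", "station_b", "rho", "flagged"])


def regrid_bilinear(field: xr.DataArray, target_lats, target_lons) -> xr.DataArray:
    """Bilinear interpolation of (time, lat, lon) onto target axes.

    Target points must lie inside the source hull (no extrapolation).
    """
    lats = np.asarray(field["lat"].values, dtype=float)
    lons = np.asarray(field["lon"].values, dtype=float)
    target_lats = np.asarray(target_lats, dtype=float)
    target_lons = np.asarray(target_lons, dtype=float)
    values = np.asarray(field.values, dtype=float)
    # RegularGridInterpolator requires ascending axes
    flip_lat = lats[0] > lats[-1] if len(lats) > 1 else False
    flip_lon = lons[0] > lons[-1] if len(lons) > 1 else False
    if flip_lat:
        lats, values = lats[::-1], values[:, ::-1, :]
    if flip_lon:
        lons, values = lons[::-1], values[:, :, ::-1]
    if target_lats.min() < lats.min() or target_lats.max() > lats.max():
        raise ValueError("target latitudes require extrapolation")
    if target_lons.min() < lons.min() or target_lons.max() > lons.max():
        raise ValueError("target longitudes require extrapolation")
    glat, glon = np.meshgrid(target_lats, target_lons, indexing="ij")
    pts = np.column_stack([glat.ravel(), glon.ravel()])
    out = np.empty((values.shape[0], len(target_lats), len(target_lons)))
    for t in range(values.shape[0]):
        itp = RegularGridInterpolator((lats, lons), values[t], method="linear")
        out[t] = itp(pts).reshape(len(target_lats), len(target_lons))
    return xr.DataArray(
        out,
        coords={"time": field["time"].values, "lat": target_lats, "lon": target_lons},
        dims=("time", "lat", "lon"),
        attrs=dict(field.attrs),
    )


def bias_correct_linear_scaling(
    esm: pd.Series,
    reference: pd.Series,
    *,
    esm_historical: pd.Series | None = None,
    multiplicative: bool = False,
) -> tuple[pd.Series, dict[int, float]]:
    """Monthly linear-scaling bias correction.

    The additive offset of month m is mean(reference, m) minus
    mean(historical ESM, m); it is applied to the entire ESM series
    (historical and scenario alike), so corrected historical monthly
    means equal the reference's monthly means exactly whenever reference
    and historical segment coincide.  A multiplicative variant (ratio of
    monthly means) is available behind the flag.

    ``esm_historical`` names the ESM segment whose climatology is
    compared with the reference; by default it is the part of ``esm``
    falling on the reference's dates (requiring a calendar overlap).
    Every month present in ``esm`` must be represented in both
    climatologies.
    """
    if esm_historical is None:
        esm_historical = esm.reindex(reference.index).dropna()
        if esm_historical.empty:
            raise ValueError("no overlap between ESM and reference series")
    ref = reference.dropna()
    offsets: dict[int, float] = {}
    esm_months = set(esm.index.month)
    for m in sorted(esm_months):
        r = ref[ref.index.month == m]
        e = esm_historical[esm_historical.index.month == m]
        if len(e) == 0 or len(r) == 0:
            raise ValueError(f"month {m} absent from the historical overlap")
        if multiplicative:
            offsets[m] = float(r.mean() / e.mean())
        else:
            offsets[m] = float(r.mean() - e.mean())
    factors = esm.index.month.map(offsets).to_numpy(dtype=float)
    corrected = esm * factors if multiplicative else esm + factors
    return corrected, offsets


def bias_correct_field(
    esm_field: xr.DataArray,
    reference_field: xr.DataArray,
    *,
    esm_historical: xr.DataArray | None = None,
) -> xr.DataArray:
    """Per-grid-cell monthly additive bias correction (for MSLP before WT).

    ``esm_historical`` defaults to the days of ``esm_field`` that fall on
    the reference's dates.
    """
    ref_t = pd.to_datetime(reference_field["time"].values)
    esm_t = pd.to_datetime(esm_field["time"].values)
    out = esm_field.values.astype(float).copy()
    if esm_historical is None:
        hist_mask = esm_t.isin(ref_t)
        if not hist_mask.any():
            raise ValueError("no overlap between ESM and reference fields")
        hist_vals, hist_t = esm_field.values[hist_mask], esm_t[hist_mask]
    else:
        hist_vals = esm_historical.values
        hist_t = pd.to_datetime(esm_historical["time"].values)
    for m in sorted(set(esm_t.month)):
        ref_m = reference_field.values[ref_t.month == m].mean(axis=0)
        hist_m = hist_vals[hist_t.month == m]
        if len(hist_m) == 0:
            raise ValueError(f"month {m} absent from the historical overlap")
        out[esm_t.month == m] += ref_m - hist_m.mean(axis=0)
    return xr.DataArray(
        out, coords=esm_field.coords, dims=esm_field.dims, attrs=dict(esm_field.attrs)
    )


def ks_two_sample(x, y, *, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    Returns (D, p, significant-at-alpha).  Used to report the
    distributional similarity of reference and bias-corrected ESM
    predictors; it never gates the pipeline.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("KS test requires non-empty samples")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def merge_standardize(
    historical: pd.Series, scenario: pd.Series
) -> tuple[pd.Series, pd.Series, Standardization]:
    """Standardize historical and scenario series with joint parameters.

    Mean and sd are computed on the concatenation and applied to both
    segments, so a warming scenario keeps its mean shift relative to the
    historical segment after standardization.
    """
    merged = pd.concat([historical, scenario])
    mu = float(merged.mean())
    sd = float(merged.std(ddof=0))
    if np.isclose(sd, 0.0):
        raise ValueError("zero standard deviation of the merged series")
    params = Standardization(mu, sd)
    h = pd.Series(params.transform(historical.to_numpy()), index=historical.index)
    s = pd.Series(params.transform(scenario.to_numpy()), index=scenario.index)
    return h, s, params
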