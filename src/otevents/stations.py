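"""Station-level preprocessing: MDA8 ozone, coverage and station pairing.

MDA8O3 (maximum daily 8-hour running mean ozone) is the regulatory
exposure metric: 8-hour running means are formed from valid hourly
concentrations and a day's value is the maximum over its running means,
provided enough of them are valid.  Ozone stations are then paired with
nearby temperature stations so that each final "station" carries both a
daily MDA8O3 and a TX series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

STATION_TYPES = ("urban", "suburban", "rural")


@dataclass(frozen=True)
class StationRecord:
    """Metadata for a single background monitoring site."""

    station_id: str
    latitude: float
    longitude: float
    altitude: float
    station_type: str
    variable: str  # "ozone" or "temperature"

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if self.station_type not in STATION_TYPES:
            raise ValueError(f"unknown station type: {self.station_type!r}")


@dataclass(frozen=True)
class StationPair:
    """An ozone site matched to a temperature site.

    Pair location metadata is taken from the ozone site.
    """

    ozone_station: StationRecord
    temperature_station: StationRecord
    distance_km: float
    altitude_difference_m: float
    coverage: float


def haversine_distance(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (Earth radius 6371.0 km)."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude out of range: {lat}")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude out of range: {lon}")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def compute_mda8(
    hourly: pd.DataFrame,
    *,
    min_valid_windows: int = 18,
    min_valid_hours_per_window: int = 6,
) -> pd.DataFrame:
    """Derive daily MDA8O3 from hourly ozone.

    Parameters
    ----------
    hourly
        DataFrame with columns ``timestamp`` (hourly datetimes), ``value``
        (ug/m3) and ``valid`` (bool).  Timestamps must be strictly
        increasing with exact one-hour spacing (gaps are not allowed; mark
        absent hours invalid instead, or pass disjoint blocks separately).
    min_valid_windows
        A day's MDA8O3 is reported only if at least this many of its 24
        running-mean windows are valid (default 18).
    min_valid_hours_per_window
        An 8-hour window is valid if at least this many of its 8 hours are
        valid (default 6, the EU convention); its mean uses valid hours only.

    Returns
    -------
    DataFrame with columns ``date`` and ``mda8o3`` (NaN where invalid).

    Notes
    -----
    Windows are labelled by their ending hour ``h`` in 1..24 of a day and
    cover hours ``h-7 .. h``, drawing the first hours from the previous
    calendar day for ``h < 8`` (EU convention).  Hours before the start of
    the supplied series count as invalid.
    """
    ts = pd.to_datetime(hourly["timestamp"].to_numpy())
    if len(ts) == 0:
        return pd.DataFrame({"date": [], "mda8o3": []})
    deltas = np.diff(ts.astype("int64"))
    if len(deltas) and not np.all(deltas == 3_600_000_000_000):
        raise ValueError("hourly series must have exact 1-hour spacing")

    values = hourly["value"].to_numpy(dtype=float)
    valid = hourly["valid"].to_numpy(dtype=bool) & np.isfinite(values)

    # Align the series to full days: hour 1 of a day is the hour beginning
    # 00:00 (i.e. timestamp 00:00), hour 24 begins at 23:00.
    first = ts[0]
    lead = int(first.hour)  # hours missing at the front of day one
    n = len(values)
    tail = (-(lead + n)) % 24
    vals = np.concatenate([np.zeros(lead), values, np.zeros(tail)])
    mask = np.concatenate(
        [np.zeros(lead, bool), valid, np.zeros(tail, bool)]
    )
    n_days = len(vals) // 24
    day0 = pd.Timestamp(first.date())

    # Pad 7 invalid hours before the first day so every window has 8 slots.
    vals = np.concatenate([np.zeros(7), np.where(mask, vals, 0.0)])
    mask = np.concatenate([np.zeros(7, bool), mask])
    win_vals = np.lib.stride_tricks.sliding_window_view(vals, 8)
    win_mask = np.lib.stride_tricks.sliding_window_view(mask, 8)
    counts = win_mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, win_vals.sum(axis=1) / counts, np.nan)
    window_ok = counts >= min_valid_hours_per_window

    means = means.reshape(n_days, 24)
    window_ok = window_ok.reshape(n_days, 24)
    n_ok = window_ok.sum(axis=1)
    day_means = np.where(window_ok, means, -np.inf).max(axis=1)
    mda8 = np.where(n_ok >= min_valid_windows, day_means, np.nan)

    dates = pd.to_datetime(day0) + pd.to_timedelta(np.arange(n_days), unit="D")
    return pd.DataFrame({"date": dates, "mda8o3": mda8})


def season_dates(years, season_months) -> pd.DatetimeIndex:
    """All calendar dates of the given season months across the given years."""
    if len(years) == 0 or len(season_months) == 0:
        raise ValueError("years and season_months must be non-empty")
    idx = pd.date_range(
        f"{min(years)}-01-01", f"{max(years)}-12-31", freq="D"
    )
    keep = idx.month.isin(list(season_months)) & idx.year.isin(list(years))
    return idx[keep]


def coverage(daily: pd.DataFrame, season_months, years) -> float:
    """Fraction of season days on which both MDA8O3 and TX are non-missing.

    ``daily`` has columns ``date``, ``mda8o3``, ``tx``.
    """
    dates = season_dates(years, season_months)
    df = daily.set_index(pd.to_datetime(daily["date"].to_numpy()))
    df = df.reindex(dates)
    ok = df["mda8o3"].notna() & df["tx"].notna()
    return float(ok.sum() / len(dates))


def pair_stations(
    ozone: list[StationRecord],
    temperature: list[StationRecord],
    pair_coverage,
    *,
    max_distance_km: float = 15.0,
    max_altitude_diff_m: float = 200.0,
    min_coverage: float = 0.75,
) -> list[StationPair]:
    """Assign to each ozone station its nearest eligible temperature station.

    Eligibility: distance <= ``max_distance_km`` and altitude difference
    <= ``max_altitude_diff_m``.  Among eligible candidates the nearest is
    chosen (ties: smaller altitude difference, then lexicographic id).
    Pairs whose joint data coverage is not strictly above ``min_coverage``
    are dropped.  If two ozone stations match the same temperature station,
    only the pair with the higher coverage is kept (tie: smaller ozone id),
    so no temperature series serves two locations.

    Parameters
    ----------
    pair_coverage
        Callable ``(ozone_id, temperature_id) -> fraction`` giving the joint
        seasonal coverage of the candidate pair.
    """
    candidates: list[StationPair] = []
    for o in ozone:
        best = None
        for t in temperature:
            d = haversine_distance(o.latitude, o.longitude, t.latitude, t.longitude)
            dz = abs(o.altitude - t.altitude)
            if d > max_distance_km or dz > max_altitude_diff_m:
                continue
            key = (d, dz, t.station_id)
            if best is None or key < best[0]:
                best = (key, t, d, dz)
        if best is None:
            continue
        _, t, d, dz = best
        cov = float(pair_coverage(o.station_id, t.station_id))
        if cov > min_coverage:
            candidates.append(StationPair(o, t, d, dz, cov))

    # Deduplicate temperature stations: keep the higher-coverage pair.
    by_temp: dict[str, StationPair] = {}
    for p in sorted(candidates, key=lambda p: (-p.coverage, p.ozone_station.station_id)):
        by_temp.setdefault(p.temperature_station.station_id, p)
    kept = sorted(by_temp.values(), key=lambda p: p.ozone_station.station_id)
    return kept


def read_hourly_csv(path) -> pd.DataFrame:
    """Hourly ozone CSV with columns station_id, timestamp, value, valid."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    df["valid"] = df["valid"].astype(bool)
    return df


def read_daily_csv(path) -> pd.DataFrame:
    """Daily series CSV with columns date, mda8o3, tx."""
    return pd.read_csv(path, parse_dates=["date"])


def pairs_to_frame(pairs: list[StationPair]) -> pd.DataFrame:
    """Tabulate pairs (location metadata from the ozone site)."""
    return pd.DataFrame(
        {
            "station_id": [p.ozone_station.station_id for p in pairs],
            "temperature_station_id": [
                p.temperature_station.station_id for p in pairs
            ],
            "latitude": [p.ozone_station.latitude for p in pairs],
            "longitude": [p.ozone_station.longitude for p in pairs],
            "altitude": [p.ozone_station.altitude for p in pairs],
            "station_type": [p.ozone_station.station_type for p in pairs],
            "distance_km": [p.distance_km for p in pairs],
            "altitude_difference_m": [p.altitude_difference_m for p in pairs],
            "coverage": [p.coverage for p in pairs],
        }
    )
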