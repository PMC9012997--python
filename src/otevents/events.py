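"""Compound ozone-temperature event definition and detection.

An *o-event* is a day whose MDA8O3 surpasses 100 ug/m3 (the WHO
guideline).  A *t-event* is a day whose TX surpasses the station's
calendar-day 80th-percentile threshold (^80TX), computed by pooling TX
over a 31-day window centred on the calendar day across all base-period
years.  A compound *o-t-event* is a day on which both occur.  Events are
coded 1 (event) / 0 (nonevent); days with a missing input are missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WHO_OZONE_THRESHOLD = 100.0  # ug/m3


@dataclass
class EventThresholds:
    """Station event thresholds.

    ``tx_thresholds`` maps (month, day) -> ^80TX in degrees C, one entry
    per calendar day of the season.
    """

    ozone_threshold: float = WHO_OZONE_THRESHOLD
    tx_thresholds: dict[tuple[int, int], float] = field(default_factory=dict)
    percentile: float = 0.80
    window_days: int = 31
    base_years: tuple[int, ...] = ()


def t_threshold(
    tx: pd.DataFrame,
    *,
    percentile: float = 0.80,
    window_days: int = 31,
    base_years=None,
    season_months=(4, 5, 6, 7, 8, 9),
    min_pool: int = 100,
) -> EventThresholds:
    """Calendar-day TX percentile thresholds (^80TX).

    For each calendar day d of the season, TX values within d +/- half
    the window are pooled across all base years and the empirical
    percentile (linear interpolation between order statistics) is taken.
    Near the season edges the window extends into out-of-season days when
    those data exist; the calendar is not wrapped.

    Parameters
    ----------
    tx
        DataFrame with columns ``date`` and ``tx``; may include
        out-of-season days, which only feed edge windows.
    min_pool
        Minimum pooled sample size per calendar day (default 100); a
        thinner pool raises ``ValueError`` naming the day.
    """
    if window_days % 2 != 1:
        raise ValueError("window_days must be odd")
    dates = pd.to_datetime(tx["date"].to_numpy())
    vals = tx["tx"].to_numpy(dtype=float)
    if base_years is None:
        base_years = sorted(set(dates.year))
    base_years = list(base_years)
    if not base_years:
        raise ValueError("base period is empty")
    half = window_days // 2

    s = pd.Series(vals, index=dates).sort_index()
    thresholds: dict[tuple[int, int], float] = {}
    season_days = sorted(
        {(d.month, d.day) for d in dates if d.month in set(season_months)}
    )
    if not season_days:
        raise ValueError("no season days present in the series")
    for month, day in season_days:
        pool = []
        for y in base_years:
            try:
                center = pd.Timestamp(year=y, month=month, day=day)
            except ValueError:  # Feb 29 in a non-leap base year
                continue
            w = s.loc[center - pd.Timedelta(days=half): center + pd.Timedelta(days=half)]
            pool.append(w.to_numpy())
        pooled = np.concatenate(pool) if pool else np.array([])
        pooled = pooled[np.isfinite(pooled)]
        if len(pooled) < min_pool:
            raise ValueError(
                f"threshold pool for calendar day {month:02d}-{day:02d} has "
                f"{len(pooled)} values (< {min_pool})"
            )
        thresholds[(month, day)] = float(
            np.quantile(pooled, percentile, method="linear")
        )
    return EventThresholds(
        tx_thresholds=thresholds,
        percentile=percentile,
        window_days=window_days,
        base_years=tuple(base_years),
    )


def detect_events(daily: pd.DataFrame, thresholds: EventThresholds) -> pd.DataFrame:
    """Detect o-, t- and compound o-t-events (strict threshold exceedance).

    ``daily`` has columns ``date``, ``mda8o3``, ``tx``; only dates covered
    by ``thresholds.tx_thresholds`` are allowed.  Returns a DataFrame with
    columns ``date``, ``o_event``, ``t_event``, ``ot_event`` (floats with
    NaN where an input is missing).
    """
    dates = pd.to_datetime(daily["date"].to_numpy())
    o3 = daily["mda8o3"].to_numpy(dtype=float)
    tx = daily["tx"].to_numpy(dtype=float)

    tx_thr = np.empty(len(dates))
    for i, d in enumerate(dates):
        key = (d.month, d.day)
        if key not in thresholds.tx_thresholds:
            raise ValueError(f"no TX threshold for calendar day {key}")
        tx_thr[i] = thresholds.tx_thresholds[key]

    o = np.where(np.isfinite(o3), (o3 > thresholds.ozone_threshold).astype(float), np.nan)
    t = np.where(np.isfinite(tx), (tx > tx_thr).astype(float), np.nan)
    ot = o * t  # NaN propagates; 1 only if both 1
    return pd.DataFrame({"date": dates, "o_event": o, "t_event": t, "ot_event": ot})


def event_summary(events: pd.DataFrame) -> dict:
    """Counts of o-, t- and o-t-event days plus the o-t-event fraction.

    Counts run over non-missing days; the fraction is o-t-event days per
    non-missing day (0 when no day is non-missing).
    """
    out = {}
    for col in ("o_event", "t_event", "ot_event"):
        out[f"n_{col.split('_')[0]}"] = int(np.nansum(events[col].to_numpy()))
    n_valid = int(events["ot_event"].notna().sum())
    out["n_days"] = n_valid
    out["ot_fraction"] = out["n_ot"] / n_valid if n_valid else 0.0
    return out
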