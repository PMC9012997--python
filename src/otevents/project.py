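"""Scenario projection of compound o-t-event frequency shifts.

Fitted station logistic models are driven with bias-corrected,
merged-standardized ESM predictor series (weather types assigned with
the trained SOM); event days are counted in 20-year time slices
(historical 1995-2014, midcentury 2041-2060, late century 2081-2100)
and reported as percent changes relative to the historical slice, with
multi-model ensemble summaries and an MT-anomaly stationarity check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .downscale import LogisticModel

DEFAULT_SLICES = {
    "historical": (1995, 2014),
    "midcentury": (2041, 2060),
    "late_century": (2081, 2100),
}


@dataclass(frozen=True)
class TimeSlice:
    name: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year - self.start_year + 1 != 20:
            raise ValueError("time slices span 20 years")


def default_slices() -> list[TimeSlice]:
    return [TimeSlice(n, a, b) for n, (a, b) in DEFAULT_SLICES.items()]


def project_events(
    model: LogisticModel,
    threshold: float,
    predictors: pd.DataFrame,
    *,
    season_months=(4, 5, 6, 7, 8, 9),
) -> pd.Series:
    """Daily event indicators from ESM predictors.

    ``predictors`` is date-indexed with one column per retained predictor
    (already bias-corrected, merged-standardized, WT via the trained SOM
    and standardized like the training data).  A day is an event iff the
    modeled probability >= threshold; only season days are scored.
    """
    in_season = predictors.index.month.isin(list(season_months))
    X = predictors.loc[in_season]
    proba = model.predict_proba(X)
    return pd.Series((proba >= threshold).astype(int), index=X.index)


def count_slice(events: pd.Series, ts: TimeSlice) -> int:
    """Event days within a time slice's seasons."""
    years = events.index.year
    if ts.start_year < years.min() or ts.end_year > years.max():
        raise ValueError(f"slice {ts.name} not covered by the event series")
    mask = (years >= ts.start_year) & (years <= ts.end_year)
    return int(events[mask].sum())


def percent_change(n_hist: int, n_future: int) -> float:
    """(n_future - n_hist) / n_hist * 100; undefined for n_hist = 0."""
    if n_hist <= 0:
        raise ValueError("percent change undefined for zero historical count")
    return (n_future - n_hist) / n_hist * 100.0


def project_station(
    model: LogisticModel,
    threshold: float,
    predictors: pd.DataFrame,
    *,
    slices: list[TimeSlice] | None = None,
    season_months=(4, 5, 6, 7, 8, 9),
) -> dict:
    """Counts per slice and percent change per future slice for one ESM run."""
    slices = slices or default_slices()
    events = project_events(model, threshold, predictors, season_months=season_months)
    counts = {ts.name: count_slice(events, ts) for ts in slices}
    hist = counts.get("historical")
    changes = {}
    for ts in slices:
        if ts.name == "historical":
            continue
        changes[ts.name] = (
            percent_change(hist, counts[ts.name]) if hist else float("nan")
        )
    return {"counts": counts, "percent_change": changes}


def ensemble_summary(changes: list[float]) -> dict:
    """Ensemble statistics of percent changes across ESMs.

    Mean/median/min/max of the signed changes plus the number of ESMs
    sharing the majority sign.
    """
    if len(changes) == 0:
        raise ValueError("no ESM results to summarize")
    arr = np.asarray(changes, dtype=float)
    signs = np.sign(arr)
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    return {
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "sign_agreement": max(n_pos, n_neg),
        "n_models": len(arr),
    }


def mt_anomaly(
    mt: pd.Series,
    *,
    slices: list[TimeSlice] | None = None,
    warning_level: float = 2.7,
    severe_level: float = 4.0,
) -> pd.DataFrame:
    """Raw MT time-slice anomalies with a stationarity flag.

    The anomaly of a future slice is its mean MT minus the historical
    slice mean (un-standardized, degrees C).  The downscaling assumes the
    trained event-predictor relation is stationary; anomalies above the
    warning level (default 2.7 C) mark projections to interpret with
    caution, above the severe level (default 4.0 C) projections whose
    stationarity assumption is doubtful.
    """
    slices = slices or default_slices()
    years = mt.index.year
    means = {}
    for ts in slices:
        seg = mt[(years >= ts.start_year) & (years <= ts.end_year)]
        if len(seg) == 0:
            raise ValueError(f"slice {ts.name} empty in the MT series")
        means[ts.name] = float(seg.mean())
    hist = means["historical"]
    rows = []
    for ts in slices:
        if ts.name == "historical":
            continue
        anom = means[ts.name] - hist
        rows.append(
            {
                "slice": ts.name,
                "anomaly": anom,
                "warning": anom > warning_level,
                "severe": anom > severe_level,
            }
        )
    return pd.DataFrame(rows)
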