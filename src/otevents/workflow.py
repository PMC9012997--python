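"""End-to-end orchestration on synthetic data.

Chains the pipeline stages into a single experiment: generate a station
network with daily series and coherent gridded fields, detect compound
o-t-events, build reanalysis-style predictors (9-cell means + SOM
weather types), fit SMOTE-balanced logistic station models, then drive
the fitted models with bias-corrected, merged-standardized pseudo-ESM
predictors to obtain time-slice frequency changes per scenario.

This is the scaffolding that the worked examples and the acceptance
checks run; every step is the public function of its stage module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import downscale, events, predictors, project, simulate, weathertypes

MET_VARS = ("GH", "MT", "SH", "SSRD")


def _season_mask(index: pd.DatetimeIndex, season_months) -> np.ndarray:
    return index.month.isin(list(season_months))


def build_training_table(
    grids: dict,
    station_row,
    daily: pd.DataFrame,
    *,
    season_months=(4, 5, 6, 7, 8, 9),
    wt_codes: pd.Series,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Predictor matrix and event outcome for one station.

    Meteorological predictors are 9-cell means standardized over the
    base-period season; the weather-type code enters as a standardized
    numeric column.  Rows with a missing outcome are dropped.
    """
    thr = events.t_threshold(daily, season_months=season_months)
    season = daily[pd.to_datetime(daily["date"]).dt.month.isin(list(season_months))]
    ev = events.detect_events(season, thr)
    ev = ev.set_index("date")

    cols = {}
    params = {}
    for var in MET_VARS:
        raw = predictors.extract_station_series(
            grids[var], station_row.latitude, station_row.longitude
        )
        raw = raw[_season_mask(raw.index, season_months)]
        z, p = predictors.standardize_series(raw)
        cols[var] = z
        params[var] = p
    wt_season = wt_codes[_season_mask(wt_codes.index, season_months)]
    z, p = predictors.standardize_series(wt_season.astype(float))
    cols["WT"] = z
    params["WT"] = p

    X = pd.DataFrame(cols)
    joined = X.join(ev["ot_event"], how="inner").dropna()
    y = joined.pop("ot_event").to_numpy(dtype=int)
    return joined, y, {"standardization": params, "thresholds": thr}


@dataclass
class ProjectionExperiment:
    """Results of a synthetic modeling + projection experiment."""

    config: simulate.SyntheticConfig
    station_models: dict  # station_id -> (LogisticModel, threshold, report|None)
    results: pd.DataFrame  # station x scenario x model percent changes
    ensembles: pd.DataFrame  # station x scenario ensemble summaries
    anomalies: pd.DataFrame  # station x scenario MT anomalies


def run_projection_experiment(
    *,
    seed: int = 0,
    n_models: int = 3,
    scenario_trends: dict[str, float] | None = None,
    stations: int = 2,
    years: tuple[int, int] = (2004, 2018),
    som_shape: tuple[int, int] = (2, 2),
    som_iterations: int = 3000,
    evaluate_models: bool = False,
    quality_gate_f1: float = 0.5,
    slices: list[project.TimeSlice] | None = None,
    config: simulate.SyntheticConfig | None = None,
) -> ProjectionExperiment:
    """Fit station models on synthetic "reanalysis" and project pseudo-ESMs.

    ``scenario_trends`` maps scenario names to MT trends in degrees C per
    decade (anchored at 2015); ``n_models`` pseudo-ESMs are generated per
    scenario by re-drawing the internal weather.  ``stations`` station
    models are fitted (taken from the first region, whose temperature
    regime produces frequent compound events).  ESM years cover the
    historical slice plus the future slices only; percent changes are
    computed per ESM and then ensemble-averaged.
    """
    slices = slices or project.default_slices()
    if config is None:
        config = simulate.SyntheticConfig(
            n_regions=2,
            stations_per_region=max(stations, 2),
            years=tuple(range(years[0], years[1] + 1)),
            grid=simulate.GridSpec(45.0, 54.0, 5.0, 16.0),
            missing_rate=0.0,
            seed=seed,
        )
    if scenario_trends is not None:
        config.warming = dict(scenario_trends)
    season = config.season_months

    network, truth = simulate.generate_network(config)
    series = simulate.generate_daily_series(config, network)
    grids = simulate.generate_grids(config, network, truth)

    # SOM weather types on base-period season MSLP
    mslp = grids["MSLP"]
    season_mask = _season_mask(pd.to_datetime(mslp["time"].values), season)
    vectors, prep = weathertypes.preprocess_mslp(mslp.values[season_mask])
    som = weathertypes.train_som(
        vectors, som_shape, iterations=som_iterations, seed=seed, preprocessing=prep
    )
    som.topographic_product = weathertypes.topographic_product(som)
    wt_codes = pd.Series(
        weathertypes.assign_wt(vectors, som),
        index=pd.to_datetime(mslp["time"].values)[season_mask],
    )

    # station models (region 1 stations: warm-summer regime, frequent events)
    chosen = network[network["region"] == 1].head(stations)
    station_models = {}
    trainings = {}
    for row in chosen.itertuples():
        X, y, aux = build_training_table(
            grids, row, series[row.station_id],
            season_months=season, wt_codes=wt_codes,
        )
        model, p_star = downscale.fit_station_model(X, y, seed=seed)
        report = None
        if evaluate_models:
            report = downscale.evaluate(X, y, folds=5, inner_folds=5, seed=seed)
            if report.f1 < quality_gate_f1:
                continue  # weak-linkage station: excluded from projection
        station_models[row.station_id] = (model, p_star, report)
        trainings[row.station_id] = (X, y, aux, row)

    # pseudo-ESM projections
    hist_years = range(slices[0].start_year, slices[0].end_year + 1)
    future_years = range(slices[1].start_year, slices[-1].end_year + 1)
    rows = []
    anom_rows = []
    for scenario in config.warming:
        for m in range(n_models):
            name = f"pseudo-esm-{m + 1:02d}"
            hist = simulate.generate_esm(
                config, network, truth, model_name=name, scenario="historical",
                years=hist_years, model_seed=m,
            )
            scen = simulate.generate_esm(
                config, network, truth, model_name=name, scenario=scenario,
                years=future_years, model_seed=m,
            )
            # weather types from per-cell bias-corrected ESM MSLP
            esm_mslp = {}
            for tag, bundle in (("hist", hist), ("scen", scen)):
                corrected = predictors.bias_correct_field(
                    bundle.fields["MSLP"], mslp,
                    esm_historical=hist.fields["MSLP"],
                )
                esm_mslp[tag] = corrected
            for sid, (model, p_star, _) in station_models.items():
                X_ref, _, aux, row = trainings[sid]
                cols_h, cols_s = {}, {}
                mt_raw = {}
                for var in MET_VARS:
                    ref = predictors.extract_station_series(
                        grids[var], row.latitude, row.longitude
                    )
                    ref = ref[_season_mask(ref.index, season)]
                    eh = predictors.extract_station_series(
                        hist.fields[var], row.latitude, row.longitude
                    )
                    es = predictors.extract_station_series(
                        scen.fields[var], row.latitude, row.longitude
                    )
                    eh = eh[_season_mask(eh.index, season)]
                    es = es[_season_mask(es.index, season)]
                    ch, offsets = predictors.bias_correct_linear_scaling(
                        eh, ref, esm_historical=eh
                    )
                    cs = es + es.index.month.map(offsets).to_numpy(dtype=float)
                    if var == "MT":
                        mt_raw = pd.concat([ch, cs])
                    zh, zs, _ = predictors.merge_standardize(ch, cs)
                    cols_h[var], cols_s[var] = zh, zs
                for tag, field in esm_mslp.items():
                    t = pd.to_datetime(field["time"].values)
                    mask = _season_mask(t, season)
                    codes = weathertypes.assign_wt(
                        prep.transform(field.values[mask]), som
                    )
                    wt = pd.Series(codes.astype(float), index=t[mask])
                    if tag == "hist":
                        wt_h = wt
                    else:
                        wt_s = wt
                zh, zs, _ = predictors.merge_standardize(wt_h, wt_s)
                cols_h["WT"], cols_s["WT"] = zh, zs
                Xh = pd.DataFrame(cols_h)
                Xs = pd.DataFrame(cols_s)
                X_esm = pd.concat([Xh, Xs]).sort_index()
                res = project.project_station(
                    model, p_star, X_esm, slices=slices, season_months=season
                )
                rows.append(
                    {
                        "station_id": sid, "scenario": scenario, "esm": name,
                        **{f"n_{k}": v for k, v in res["counts"].items()},
                        **{f"change_{k}": v for k, v in res["percent_change"].items()},
                    }
                )
                anom = project.mt_anomaly(mt_raw, slices=slices)
                for a in anom.itertuples():
                    anom_rows.append(
                        {"station_id": sid, "scenario": scenario, "esm": name,
                         "slice": a.slice, "anomaly": a.anomaly,
                         "warning": a.warning, "severe": a.severe}
                    )

    results = pd.DataFrame(rows)
    ens_rows = []
    for (sid, scenario), grp in results.groupby(["station_id", "scenario"]):
        for ts in slices[1:]:
            s = project.ensemble_summary(grp[f"change_{ts.name}"].tolist())
            ens_rows.append(
                {"station_id": sid, "scenario": scenario, "slice": ts.name, **s}
            )
    ensembles = pd.DataFrame(ens_rows)
    anomalies = pd.DataFrame(anom_rows)
    return ProjectionExperiment(config, station_models, results, ensembles, anomalies)
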