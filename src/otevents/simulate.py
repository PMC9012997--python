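"""Synthetic study systems with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
a network of background stations grouped into regions; per-station daily
TX driven by a seasonal cycle plus a region-shared AR(1) synoptic term
(so regionalization has a signal to find); MDA8O3 responding linearly
and positively to TX with region-specific slope; daily gridded fields
(MSLP with planted recurring pressure patterns, MT coherent with station
TX in the 9-cell neighborhood, plus GH/SH/SSRD co-varying with the
synoptic state); and pseudo-ESM runs equal to the truth process plus
known additive monthly biases and scenario-specific warming trends.
Every planted label and parameter is recorded in :class:`GroundTruth`,
so downstream recovery can be scored without re-deriving anything.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

SEASON_MONTHS = (4, 5, 6, 7, 8, 9)


@dataclass
class RegionParams:
    """Per-region generative parameters.

    tx_mean / tx_amplitude in degrees C; ar_coef and ar_sd shape the
    shared synoptic AR(1) term; ot_slope is the ozone response to TX in
    ug/m3 per degree C; ozone_sd the residual ozone noise.
    """

    tx_mean: float
    tx_amplitude: float = 6.0
    ar_coef: float = 0.7
    ar_sd: float = 2.0
    ot_slope: float = 3.0
    ozone_sd: float = 8.0
    ozone_intercept: float | None = None  # default: 90 - ot_slope * tx_mean

    def intercept(self) -> float:
        if self.ozone_intercept is not None:
            return self.ozone_intercept
        return 90.0 - self.ot_slope * self.tx_mean


@dataclass
class GridSpec:
    lat_min: float = 45.0
    lat_max: float = 60.0
    lon_min: float = 0.0
    lon_max: float = 20.0
    step: float = 1.0

    def lats(self) -> np.ndarray:
        return np.arange(self.lat_min, self.lat_max + self.step / 2, self.step)

    def lons(self) -> np.ndarray:
        return np.arange(self.lon_min, self.lon_max + self.step / 2, self.step)


@dataclass
class SyntheticConfig:
    n_regions: int = 6
    stations_per_region: int = 10
    years: tuple[int, ...] = tuple(range(2004, 2019))
    season_months: tuple[int, ...] = SEASON_MONTHS
    region_params: list[RegionParams] | None = None
    grid: GridSpec = field(default_factory=GridSpec)
    n_patterns: int = 4
    station_noise_sd: float = 1.0
    mslp_pattern_amplitude: float = 10.0  # hPa
    mslp_noise_sd: float = 1.0  # hPa
    grid_noise_sd: float = 0.5
    missing_rate: float = 0.05
    esm_bias: dict | None = None  # variable -> {month -> additive offset}
    warming: dict | None = None  # scenario -> trend in C per decade from 2015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.stations_per_region < 1:
            raise ValueError("stations_per_region must be >= 1")
        if len(self.season_months) == 0:
            raise ValueError("season_months must be non-empty")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.region_params is None:
            means = np.linspace(14.0, 26.0, self.n_regions)
            self.region_params = [RegionParams(tx_mean=float(m)) for m in means]
        if len(self.region_params) != self.n_regions:
            raise ValueError("region_params length must equal n_regions")
        for rp in self.region_params:
            if rp.ar_sd <= 0 or rp.ozone_sd <= 0:
                raise ValueError("all noise standard deviations must be > 0")
        if self.station_noise_sd <= 0 or self.mslp_noise_sd < 0:
            raise ValueError("station_noise_sd must be > 0")
        if self.esm_bias is None:
            self.esm_bias = {"MT": {6: 2.0, 7: 1.5}, "SH": {}, "GH": {},
                             "SSRD": {}, "MSLP": {}}
        if self.warming is None:
            self.warming = {"SSP245": 0.30, "SSP370": 0.55}
        if len(self.grid.lats()) < 3 or len(self.grid.lons()) < 3:
            raise ValueError("grid too small for 9-cell neighborhoods")


@dataclass
class GroundTruth:
    region_labels: dict[str, int]
    pattern_labels: pd.Series | None = None  # date -> planted MSLP pattern
    true_coefficients: dict[str, float] | None = None
    esm_bias: dict | None = None
    warming: dict | None = None


def _rng(config_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, *key])


def generate_network(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Station metadata with planted region membership.

    Region centers are spread over the grid interior; stations jitter
    around their center, with non-negative altitudes and background types
    cycling urban / suburban / rural.
    """
    rng = _rng(config.seed, 1)
    g = config.grid
    margin = 2.0
    n = config.n_regions
    # region centers on a rough lattice inside the domain
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    lat_c = np.linspace(g.lat_min + margin, g.lat_max - margin, nrow)
    lon_c = np.linspace(g.lon_min + margin, g.lon_max - margin, ncol)
    centers = [(lat_c[i // ncol], lon_c[i % ncol]) for i in range(n)]

    types = ("urban", "suburban", "rural")
    rows = []
    labels = {}
    for r, (clat, clon) in enumerate(centers, start=1):
        for s in range(config.stations_per_region):
            sid = f"R{r}S{s:02d}"
            rows.append(
                {
                    "station_id": sid,
                    "latitude": float(np.clip(clat + rng.uniform(-1.2, 1.2),
                                              g.lat_min, g.lat_max)),
                    "longitude": float(np.clip(clon + rng.uniform(-1.2, 1.2),
                                               g.lon_min, g.lon_max)),
                    "altitude": float(rng.exponential(150.0)),
                    "station_type": types[s % 3],
                    "region": r,
                }
            )
            labels[sid] = r
    network = pd.DataFrame(rows)
    truth = GroundTruth(region_labels=labels, esm_bias=config.esm_bias,
                        warming=config.warming)
    return network, truth


def _dates(years) -> pd.DatetimeIndex:
    return pd.date_range(f"{min(years)}-01-01", f"{max(years)}-12-31", freq="D")


def _seasonal(dates: pd.DatetimeIndex, mean: float, amplitude: float) -> np.ndarray:
    doy = dates.dayofyear.to_numpy()
    return mean + amplitude * np.cos(2 * np.pi * (doy - 196) / 365.25)


def _ar1(n: int, coef: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    innov = rng.normal(0.0, sd, size=n)
    x = np.empty(n)
    x[0] = innov[0] / np.sqrt(max(1.0 - coef**2, 1e-12))
    for t in range(1, n):
        x[t] = coef * x[t - 1] + innov[t]
    return x


def synoptic_terms(
    config: SyntheticConfig, years, *, seed_key: int = 2
) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Region-shared AR(1) synoptic anomalies, one row per region.

    Deterministic in (config.seed, seed_key, years); station series and
    gridded MT use the same terms so they are coherent by construction.
    """
    dates = _dates(years)
    rng = _rng(config.seed, seed_key, min(years), max(years))
    out = np.vstack(
        [
            _ar1(len(dates), rp.ar_coef, rp.ar_sd, rng)
            for rp in config.region_params
        ]
    )
    return dates, out


def generate_daily_series(
    config: SyntheticConfig,
    network: pd.DataFrame,
    *,
    synoptic: tuple[pd.DatetimeIndex, np.ndarray] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-station daily TX and MDA8O3 over the configured years.

    TX = region seasonal cycle + shared region synoptic AR(1) + station
    noise; MDA8O3 = region intercept + slope * TX + noise.  Missingness
    is injected completely at random at ``config.missing_rate`` per
    variable.
    """
    if synoptic is None:
        synoptic = synoptic_terms(config, config.years)
    dates, syn = synoptic
    out: dict[str, pd.DataFrame] = {}
    for row in network.itertuples():
        if row.region < 1 or row.region > config.n_regions:
            raise KeyError(f"station {row.station_id} has unknown region {row.region}")
        rp = config.region_params[row.region - 1]
        rng = _rng(config.seed, 3, zlib.crc32(row.station_id.encode()))
        tx = (
            _seasonal(dates, rp.tx_mean, rp.tx_amplitude)
            + syn[row.region - 1]
            + rng.normal(0.0, config.station_noise_sd, len(dates))
        )
        o3 = rp.intercept() + rp.ot_slope * tx + rng.normal(0.0, rp.ozone_sd, len(dates))
        tx = tx.astype(float)
        o3 = o3.astype(float)
        if config.missing_rate > 0:
            tx[rng.uniform(size=len(dates)) < config.missing_rate] = np.nan
            o3[rng.uniform(size=len(dates)) < config.missing_rate] = np.nan
        out[row.station_id] = pd.DataFrame(
            {"date": dates, "mda8o3": o3, "tx": tx}
        )
    return out


def _pattern_bases(config: SyntheticConfig) -> np.ndarray:
    """Smooth planted MSLP basis fields, (n_patterns, nlat, nlon)."""
    rng = _rng(config.seed, 4)
    lats, lons = config.grid.lats(), config.grid.lons()
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    u = (glat - lats.min()) / max(np.ptp(lats), 1e-9)
    v = (glon - lons.min()) / max(np.ptp(lons), 1e-9)
    bases = []
    for _ in range(config.n_patterns):
        f1, f2 = rng.uniform(0.5, 1.5, 2)
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        sgn = rng.choice([-1.0, 1.0])
        bases.append(
            1013.0
            + sgn * config.mslp_pattern_amplitude
            * np.sin(2 * np.pi * f1 * u + p1) * np.cos(2 * np.pi * f2 * v + p2)
        )
    return np.stack(bases)


def _region_footprints(config: SyntheticConfig, network: pd.DataFrame) -> np.ndarray:
    """Gaussian spatial weight of each region's synoptic term, (n_regions, nlat, nlon)."""
    lats, lons = config.grid.lats(), config.grid.lons()
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    foot = []
    for r in range(1, config.n_regions + 1):
        members = network[network["region"] == r]
        clat = members["latitude"].mean()
        clon = members["longitude"].mean()
        d2 = (glat - clat) ** 2 + (glon - clon) ** 2
        foot.append(np.exp(-d2 / (2 * 3.0**2)))
    return np.stack(foot)


def generate_grids(
    config: SyntheticConfig,
    network: pd.DataFrame,
    truth: GroundTruth,
    *,
    years=None,
    seed_key: int = 5,
    synoptic: tuple[pd.DatetimeIndex, np.ndarray] | None = None,
) -> dict[str, xr.DataArray]:
    """Daily gridded MSLP, MT, GH, SH and SSRD coherent with station events.

    MSLP days draw one of the planted basis patterns plus noise (labels
    recorded in ``truth.pattern_labels``); MT spatially interpolates the
    region synoptic terms (so 9-cell means track station TX); GH, SH and
    SSRD co-vary with the synoptic state with variable-specific gains.
    """
    years = config.years if years is None else years
    if synoptic is None:
        synoptic = synoptic_terms(config, years)
    dates, syn = synoptic
    lats, lons = config.grid.lats(), config.grid.lons()
    rng = _rng(config.seed, seed_key, min(years), max(years))
    n_days = len(dates)

    bases = _pattern_bases(config)
    labels = rng.integers(0, config.n_patterns, size=n_days)
    mslp = bases[labels] + rng.normal(0.0, config.mslp_noise_sd,
                                      (n_days, len(lats), len(lons)))
    truth.pattern_labels = pd.Series(labels, index=dates)

    foot = _region_footprints(config, network)
    # weighted synoptic mixture per day and cell
    mix = np.einsum("rd,rij->dij", syn, foot)
    seas = _seasonal(dates, 0.0, 1.0)[:, None, None]  # unit seasonal shape
    mean_tx = float(np.mean([rp.tx_mean for rp in config.region_params]))
    amp = float(np.mean([rp.tx_amplitude for rp in config.region_params]))

    def noise():
        return rng.normal(0.0, config.grid_noise_sd, (n_days, len(lats), len(lons)))

    def own_weather(scale):
        # variable-specific synoptic variability independent of the thermal
        # state, so the predictors are correlated but not collinear
        return scale * rng.standard_normal(n_days)[:, None, None]

    fields = {
        "MSLP": mslp,
        # 850-hPa air temperature sits ~8 C below the surface maximum
        "MT": (mean_tx - 8.0) + amp * seas + mix + noise(),
        "GH": 1500.0 + 25.0 * seas + 2.0 * mix + own_weather(10.0) + 4.0 * noise(),
        "SH": 0.006 + 0.002 * seas - 0.0003 * mix + own_weather(0.0012)
        + 0.0002 * noise(),
        "SSRD": 220.0 + 90.0 * seas + 5.0 * mix + own_weather(35.0)
        + 10.0 * noise(),
    }
    units = {"MSLP": "hPa", "MT": "degC", "GH": "m", "SH": "kg kg-1",
             "SSRD": "W m-2"}
    return {
        var: xr.DataArray(
            arr,
            coords={"time": dates, "lat": lats, "lon": lons},
            dims=("time", "lat", "lon"),
            attrs={"units": units[var], "long_name": var},
        )
        for var, arr in fields.items()
    }


@dataclass
class ESMBundle:
    """One pseudo-ESM run: gridded fields for a scenario (or historical)."""

    model_name: str
    scenario: str
    fields: dict[str, xr.DataArray]


def generate_esm(
    config: SyntheticConfig,
    network: pd.DataFrame,
    truth: GroundTruth,
    *,
    model_name: str = "pseudo-esm-01",
    scenario: str = "historical",
    years=None,
    model_seed: int = 0,
) -> ESMBundle:
    """A pseudo-ESM run = truth process + monthly biases (+ warming trend).

    The run re-draws the synoptic/pattern noise with a model-specific seed
    (distinct pseudo-models have distinct internal weather), adds the
    configured per-month additive bias to every variable, and for scenario
    runs adds a linear MT warming trend (``config.warming``, degrees C per
    decade, anchored at 2015; historical years are trend-free).
    """
    if scenario != "historical" and scenario not in config.warming:
        raise ValueError(f"scenario {scenario!r} not configured")
    if years is None:
        years = range(1995, 2015) if scenario == "historical" else range(2015, 2101)
    seed_key = 1000 + 17 * model_seed
    synoptic = synoptic_terms(config, years, seed_key=seed_key)
    fields = generate_grids(
        config, network, GroundTruth(region_labels=truth.region_labels),
        years=years, seed_key=seed_key + 1, synoptic=synoptic,
    )
    dates = pd.to_datetime(fields["MT"]["time"].values)
    months = dates.month
    for var, da in fields.items():
        bias = config.esm_bias.get(var, {})
        if bias:
            offsets = np.array([bias.get(int(m), 0.0) for m in months])
            da.values[:] = da.values + offsets[:, None, None]
    if scenario != "historical":
        trend = config.warming[scenario]
        frac_years = np.asarray((dates - pd.Timestamp("2015-01-01")).days) / 365.25
        warm = trend * np.maximum(frac_years, 0.0) / 10.0
        fields["MT"].values[:] = fields["MT"].values + warm[:, None, None]
    return ESMBundle(model_name=model_name, scenario=scenario, fields=fields)


def generate_logistic_training(
    coefficients: dict[str, float],
    n: int,
    *,
    intercept: float = -2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Synthetic standardized predictors and Bernoulli outcomes.

    Predictor columns are iid standard normal; the event probability is
    logistic in ``intercept + X @ coefficients``.  With the default
    intercept the event rate is realistically imbalanced (minority class
    well under 50%).
    """
    rng = np.random.default_rng(seed)
    names = list(coefficients)
    X = pd.DataFrame(rng.normal(size=(n, len(names))), columns=names)
    eta = intercept + X.to_numpy() @ np.array([coefficients[c] for c in names])
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.uniform(size=n) < p).astype(int)
    return X, y


# ---------------------------------------------------------------------------
# plain-text artifact writers

def save_network_csv(network: pd.DataFrame, path) -> None:
    network.to_csv(path, index=False)


def save_series_csv(series: dict[str, pd.DataFrame], directory) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for sid, df in series.items():
        df.to_csv(d / f"{sid}.csv", index=False)


def save_grid_netcdf(field: xr.DataArray, path) -> None:
    field.to_dataset(name=str(field.attrs.get("long_name", "field"))).to_netcdf(
        path, engine="scipy"
    )


def save_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "region_labels": truth.region_labels,
        "pattern_labels": (
            {str(k.date()): int(v) for k, v in truth.pattern_labels.items()}
            if truth.pattern_labels is not None
            else None
        ),
        "true_coefficients": truth.true_coefficients,
        "esm_bias": truth.esm_bias,
        "warming": truth.warming,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
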