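import numpy as np
import pandas as pd
import pytest

from otevents import simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SyntheticConfig(
        n_regions=2, stations_per_region=3, years=(2004, 2005, 2006), seed=7
    )


@pytest.fixture(scope="session")
def small_network(small_config):
    return simulate.generate_network(small_config)


@pytest.fixture(scope="session")
def small_series(small_config, small_network):
    network, _ = small_network
    return simulate.generate_daily_series(small_config, network)


def random_hourly_days(n_days, seed, *, valid_rate=0.8, start="2010-06-01"):
    """Continuous hourly ozone block with random validity, for MDA8 checks."""
    rng = np.random.default_rng(seed)
    ts = pd.date_range(start, periods=24 * n_days, freq="h")
    values = rng.uniform(0, 150, size=len(ts))
    valid = rng.uniform(size=len(ts)) < valid_rate
    return pd.DataFrame({"timestamp": ts, "value": values, "valid": valid})


def mda8_bruteforce(hourly, *, min_valid_windows=18, min_valid_hours=6):
    """Enumerate every 8-hour window explicitly (independent oracle)."""
    ts = pd.to_datetime(hourly["timestamp"].to_numpy())
    lookup = {t: (v, bool(ok)) for t, v, ok in
              zip(ts, hourly["value"], hourly["valid"])}
    days = sorted({pd.Timestamp(t.date()) for t in ts})
    out = {}
    for day in days:
        windows = []
        for h in range(1, 25):  # window ends at hour h, covers h-7..h
            end = day + pd.Timedelta(hours=h - 1)  # timestamp of last hour
            vals = []
            for back in range(8):
                t = end - pd.Timedelta(hours=back)
                if t in lookup and lookup[t][1] and np.isfinite(lookup[t][0]):
                    vals.append(lookup[t][0])
            if len(vals) >= min_valid_hours:
                windows.append(np.mean(vals))
        out[day] = max(windows) if len(windows) >= min_valid_windows else np.nan
    return out
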