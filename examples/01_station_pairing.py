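"""Derive MDA8 ozone from hourly data and pair ozone/temperature stations.

MDA8O3 is the maximum over a day's 8-hour running means; a day is valid
only if at least 18 of its 24 windows are valid.  Ozone stations are then
paired to temperature stations within 15 km and 200 m altitude difference,
keeping pairs with more than 75% joint seasonal coverage.
"""

import numpy as np
import pandas as pd

from otevents import stations

# --- a week of hourly ozone with a midday peak and some invalid hours
rng = np.random.default_rng(0)
ts = pd.date_range("2012-06-01", periods=24 * 7, freq="h")
diurnal = 70 + 40 * np.sin(np.pi * ((ts.hour - 6) % 24) / 14)
hourly = pd.DataFrame(
    {
        "timestamp": ts,
        "value": diurnal + rng.normal(0, 5, len(ts)),
        "valid": rng.uniform(size=len(ts)) > 0.1,
    }
)
mda8 = stations.compute_mda8(hourly)
print("Daily MDA8O3 (ug/m3):")
print(mda8.to_string(index=False))
print("Each value is the largest valid 8-hour running mean of its day;"
      " NaN would mark a day with fewer than 18 valid windows.\n")

# --- pairing: the nearest eligible temperature station wins
ozone = [
    stations.StationRecord("O_city", 48.15, 11.55, 520, "urban", "ozone"),
    stations.StationRecord("O_edge", 48.05, 11.65, 540, "suburban", "ozone"),
]
temperature = [
    stations.StationRecord("T_close", 48.14, 11.57, 515, "urban", "temperature"),
    stations.StationRecord("T_far", 48.40, 11.90, 460, "rural", "temperature"),
]
coverages = {("O_city", "T_close"): 0.93, ("O_edge", "T_close"): 0.88}
pairs = stations.pair_stations(
    ozone, temperature, lambda o, t: coverages.get((o, t), 0.0)
)
print(stations.pairs_to_frame(pairs).to_string(index=False))
print("Both ozone sites matched T_close, so only the higher-coverage pair"
      " (O_city, 0.93) is kept; T_far is outside the 15-km limit.")
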