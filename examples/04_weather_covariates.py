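"""Weather alignment: daily means, twilight windows, snow bookkeeping.

Simulates a winter month of 5-min weather, builds the calendar-day
covariate table used by activity-level models and the dusk-centered 5-h
windows used by timing models, and shows the inclusive 8 cm snow rule.
"""

import numpy as np
import pandas as pd

from noctograph.synthetic import SimConfig, simulate_weather
from noctograph.twilight import FLAGSTAFF, twilight_table
from noctograph.weather import (
    daily_covariate_table,
    daily_snow_series,
    twilight_window_table,
)

rng = np.random.default_rng(11)
weather = simulate_weather(SimConfig(), "2015-12-01", "2015-12-14", rng)
dates = pd.date_range("2015-12-01", "2015-12-14")

daily = daily_covariate_table(weather, dates)
print("daily covariates (temp mean, sqrt precip, snow category):")
print(daily[["temp_c", "wind_ms", "precip_sqrt", "snow_cm", "snow_cat"]]
      .round(2).to_string())

deep = daily_snow_series(weather) >= 8.0
print(f"\ndays at/above the 8 cm snow boundary: {int(deep.sum())} of {len(dates)}")

twi = twilight_table(FLAGSTAFF, "2015-12-01", "2015-12-05")
dusk_windows = twilight_window_table(weather, twi.frame["civil_dusk"])
print("\n5-h dusk-window covariates (61 records each):")
print(dusk_windows[["twilight", "n_records", "temp_c", "wind_ms"]]
      .round(2).to_string(index=False))
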