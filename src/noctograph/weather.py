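"""Alignment of 5-min weather records to analysis units.

Two windows matter: calendar-day means feed the activity-level (daily
ODBA) models, while 5-h windows centered on civil twilight feed the
activity-timing models, since conditions around dusk/dawn are what an
animal deciding when to leave its den experiences.  Precipitation enters
models as the square root of the daily total (rain volumes are strongly
right-skewed), snow cover as a two-level category split at 8 cm
(inclusive), and wind chill as the plain temperature x wind product.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .core import SNOW_CATEGORIES, ValidationError

CADENCE = pd.Timedelta(minutes=5)
RECORDS_PER_DAY = int(pd.Timedelta(days=1) / CADENCE)

#: Inclusive snow-depth boundary (cm) between the two snow categories.
SNOW_THRESHOLD_CM = 8.0


def snow_category(snow_cm: float) -> str:
    """``'ge8cm'`` when snow cover is at least 8 cm, else ``'lt8cm'``."""
    if not np.isfinite(snow_cm):
        raise ValidationError("snow depth is missing")
    return "ge8cm" if snow_cm >= SNOW_THRESHOLD_CM else "lt8cm"


def wind_chill_interaction(temp_c, wind_ms):
    """Wind-chill effect as the temperature x wind product term."""
    return np.asarray(temp_c, dtype=float) * np.asarray(wind_ms, dtype=float)


def daily_covariates(
    weather: pd.DataFrame, date, min_coverage: float = 0.8
) -> dict:
    """Calendar-day covariate means for one date.

    Returns temp/wind means, ``precip_sqrt`` (square root of the daily
    precipitation total in mm), the snow category, the coverage fraction,
    and ``complete`` (False when coverage is below ``min_coverage``, in
    which case the means are flagged missing).
    """
    date = pd.Timestamp(date).normalize()
    day = weather[(weather.index >= date) & (weather.index < date + pd.Timedelta(days=1))]
    coverage = day["temp_c"].notna().sum() / RECORDS_PER_DAY
    complete = coverage >= min_coverage
    snow_vals = day["snow_cm"].dropna()
    snow_cm = float(snow_vals.iloc[0]) if len(snow_vals) else np.nan
    out = {
        "date": date,
        "coverage": float(coverage),
        "complete": bool(complete),
        "snow_cm": snow_cm,
        "snow_cat": snow_category(snow_cm) if np.isfinite(snow_cm) else None,
    }
    if complete:
        out["temp_c"] = float(day["temp_c"].mean())
        out["wind_ms"] = float(day["wind_ms"].mean())
        out["precip_sqrt"] = float(np.sqrt(day["precip_mm"].sum()))
    else:
        out["temp_c"] = out["wind_ms"] = out["precip_sqrt"] = np.nan
    return out


def daily_covariate_table(weather: pd.DataFrame, dates: Iterable) -> pd.DataFrame:
    rows = [daily_covariates(weather, d) for d in dates]
    return pd.DataFrame(rows).set_index("date")


def twilight_window_covariates(
    weather: pd.DataFrame, twilight_time, width_h: float = 5.0
) -> dict:
    """Covariate means over a window centered on a twilight time.

    The window is ``[t - width/2, t + width/2]`` with inclusive endpoints
    (61 cadence records for the default 5-h width).  A window extending
    beyond the record is not an error: the mean over the available records
    is returned with the coverage fraction and ``complete=False``.
    """
    t = pd.Timestamp(twilight_time)
    half = pd.Timedelta(hours=width_h / 2.0)
    window = weather[(weather.index >= t - half) & (weather.index <= t + half)]
    expected = int(round(width_h * 3600 / CADENCE.total_seconds())) + 1
    n = int(window["temp_c"].notna().sum())
    coverage = n / expected
    out = {
        "twilight": t,
        "coverage": float(coverage),
        "complete": coverage >= 1.0 - 1e-9,
        "n_records": n,
    }
    if n:
        out["temp_c"] = float(window["temp_c"].mean())
        out["wind_ms"] = float(window["wind_ms"].mean())
        out["precip_mm"] = float(window["precip_mm"].sum())
        out["precip_sqrt"] = float(np.sqrt(max(out["precip_mm"], 0.0)))
    else:
        out["temp_c"] = out["wind_ms"] = out["precip_mm"] = out["precip_sqrt"] = np.nan
    return out


def twilight_window_table(
    weather: pd.DataFrame, twilight_times: Iterable, width_h: float = 5.0
) -> pd.DataFrame:
    rows = [twilight_window_covariates(weather, t, width_h) for t in twilight_times]
    return pd.DataFrame(rows)


def daily_snow_series(weather: pd.DataFrame) -> pd.Series:
    """Per-day snow depth (first reading of each day; the source reports
    one value per day, replicated across the cadence grid)."""
    daily = weather["snow_cm"].groupby(weather.index.normalize()).first()
    daily.index.name = "date"
    return daily
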