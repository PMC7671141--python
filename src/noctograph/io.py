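"""Readers and writers for the delimited interchange formats.

Trace files:    ``timestamp,x,y,z``            ISO 8601 local time, axes in g
Weather files:  ``timestamp,temp_c,wind_ms,precip_mm,snow_cm``  5-min cadence
Twilight files: ``date,civil_dawn,civil_dusk``

All parsing goes through pandas; validation (duplicates, ordering, declared
vs inferred sampling rate) is done here so downstream code can assume
well-formed containers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import AccelTrace, ParseError, TwilightTable, ValidationError

TRACE_COLUMNS = ["timestamp", "x", "y", "z"]
WEATHER_COLUMNS = ["timestamp", "temp_c", "wind_ms", "precip_mm", "snow_cm"]

#: Relative tolerance between declared rate and inferred median spacing.
RATE_TOLERANCE = 0.01


def _read_csv(path, columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return frame


def _parse_timestamps(frame: pd.DataFrame, column: str, path) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(frame[column], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(parsed.isna().to_numpy())
    if bad.size:
        # +2: one for the header line, one for 1-based numbering.
        line = int(bad[0]) + 2
        raise ParseError(
            f"{path}: malformed timestamp {frame[column].iloc[bad[0]]!r} at line {line}"
        )
    return pd.DatetimeIndex(parsed)


def read_trace(path, rate_hz: float, animal_id: str = "", sex: str = "female") -> AccelTrace:
    """Read and validate a tri-axial trace file.

    Out-of-order or duplicated timestamps are rejected; a >1% mismatch
    between the declared rate and the median inferred spacing is a
    validation error.  Gaps on the sampling grid become NaN samples.
    """
    frame = _read_csv(path, TRACE_COLUMNS)
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & frame[col].notna().to_numpy())
        if bad.size:
            raise ParseError(
                f"{path}: malformed value {frame[col].iloc[bad[0]]!r} in column "
                f"{col!r} at line {int(bad[0]) + 2}"
            )
        frame[col] = vals
    times = _parse_timestamps(frame, "timestamp", path)
    if len(times) == 0:
        raise ParseError(f"{path}: empty trace file")
    if times.duplicated().any():
        dup = times[times.duplicated()][0]
        raise ValidationError(f"{path}: duplicated timestamp {dup}")
    if not times.is_monotonic_increasing:
        raise ValidationError(f"{path}: timestamps are not strictly increasing")

    step = pd.Timedelta(seconds=1.0 / rate_hz)
    if len(times) > 1:
        spacing = np.diff(times.asi8)  # ns
        median = float(np.median(spacing))
        expected = step.value
        if abs(median - expected) > RATE_TOLERANCE * expected:
            raise ValidationError(
                f"{path}: declared rate {rate_hz} Hz implies spacing "
                f"{expected / 1e9:.3f} s but median inferred spacing is "
                f"{median / 1e9:.3f} s"
            )

    # Reindex onto the regular grid so gaps are explicit NaN samples.
    start = times[0]
    pos = np.round((times.asi8 - start.value) / step.value)
    if np.max(np.abs((times.asi8 - start.value) - pos * step.value)) > 0.01 * step.value:
        raise ValidationError(f"{path}: timestamps do not align to a {rate_hz} Hz grid")
    n = int(pos[-1]) + 1
    axes = {}
    for col in ("x", "y", "z"):
        arr = np.full(n, np.nan)
        arr[pos.astype(int)] = frame[col].to_numpy(dtype=float)
        axes[col] = arr
    return AccelTrace(
        animal_id=animal_id, sex=sex, start=start, rate_hz=rate_hz, **axes
    )


def write_trace(trace: AccelTrace, path) -> None:
    """Write a trace, dropping gap rows so read_trace round-trips it."""
    times = trace.times()
    keep = ~trace.missing_mask()
    frame = pd.DataFrame(
        {
            "timestamp": times[keep].strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3],
            "x": trace.x[keep],
            "y": trace.y[keep],
            "z": trace.z[keep],
        }
    )
    frame.to_csv(path, index=False, float_format="%.6f")


def read_weather(path) -> pd.DataFrame:
    """Read a weather file into a 5-min-cadence frame indexed by timestamp."""
    frame = _read_csv(path, WEATHER_COLUMNS)
    times = _parse_timestamps(frame, "timestamp", path)
    if times.duplicated().any():
        raise ValidationError(f"{path}: duplicated weather timestamp")
    out = frame.drop(columns=["timestamp"]).set_index(times).sort_index()
    for col in ("precip_mm", "snow_cm"):
        vals = out[col].dropna()
        if (vals < 0).any():
            raise ValidationError(f"{path}: negative values in {col}")
    return out


def write_weather(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index=False, float_format="%.4f")


def read_twilight(path) -> TwilightTable:
    frame = _read_csv(path, ["date", "civil_dawn", "civil_dusk"])
    dates = pd.DatetimeIndex(
        pd.to_datetime(frame["date"], errors="coerce", format="ISO8601")
    )
    if dates.isna().any():
        raise ParseError(f"{path}: malformed date in twilight table")
    table = pd.DataFrame(
        {
            "civil_dawn": pd.to_datetime(frame["civil_dawn"], format="ISO8601").to_numpy(),
            "civil_dusk": pd.to_datetime(frame["civil_dusk"], format="ISO8601").to_numpy(),
        },
        index=dates.normalize(),
    )
    return TwilightTable(frame=table)


def write_twilight(table: TwilightTable, path) -> None:
    out = pd.DataFrame(
        {
            "date": table.frame.index.strftime("%Y-%m-%d"),
            "civil_dawn": table.frame["civil_dawn"].dt.strftime("%Y-%m-%dT%H:%M:%S"),
            "civil_dusk": table.frame["civil_dusk"].dt.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    )
    out.to_csv(path, index=False)
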