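"""Core domain containers and the noon-to-noon day convention.

The analysis treats an *animal-night* — local noon to the following local
noon — as its unit for activity timing, so that a nocturnal bout spanning
midnight is never split across rows.  "Mean daily ODBA", in contrast, is a
calendar-day (midnight-to-midnight) quantity so that it aligns with daily
weather covariates.  Both conventions are implemented here and used
consistently by the downstream modules.

All timestamps are fixed local standard time (no DST transitions within a
deployment): the clock-time plausibility windows applied to activity onsets
and offsets are civil clock times.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SEXES = ("female", "male")
STAGES = ("winter", "mating", "lactation", "fattening")
SNOW_CATEGORIES = ("lt8cm", "ge8cm")

#: Quality flags attached to :class:`ActivityDay` rows.
FLAG_NO_DETECTION = "no_detection"
FLAG_ONSET_OUT_OF_WINDOW = "onset_out_of_window"
FLAG_OFFSET_OUT_OF_WINDOW = "offset_out_of_window"
FLAG_SNOW_EXCLUDED = "snow_excluded"
FLAG_SNOW_UNRESOLVED = "snow_unresolved"
FLAG_LOW_COVERAGE = "low_coverage"

#: Default local clock time opening each animal-night.
DAY_BOUNDARY = dt.time(12, 0)


class ValidationError(ValueError):
    """An input violated a structural invariant of a domain type."""


class ParseError(ValueError):
    """A delimited input file could not be parsed."""


def _as_timestamp(value) -> pd.Timestamp:
    ts = pd.Timestamp(value)
    if ts.tzinfo is not None:
        raise ValidationError(
            "timestamps must be naive local standard time, got tz-aware "
            f"{ts!r}"
        )
    return ts


@dataclasses.dataclass
class AccelTrace:
    """Uniformly sampled tri-axial acceleration for one animal-deployment.

    Axes are in g.  Gaps are explicit: a missing sample is NaN on all three
    axes at its grid position, never a silent jump in time.

    Parameters
    ----------
    animal_id : opaque label for the individual.
    sex : ``"female"`` or ``"male"``.
    start : first sample's timestamp (naive, local standard time).
    rate_hz : sampling frequency in Hz; the study's devices ran at 1 or 10.
    x, y, z : equal-length acceleration sequences in g.
    """

    animal_id: str
    sex: str
    start: pd.Timestamp
    rate_hz: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.rate_hz > 0:
            raise ValidationError(f"rate_hz must be positive, got {self.rate_hz}")
        self.start = _as_timestamp(self.start)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.x)
        if n < 1:
            raise ValidationError("trace must contain at least one sample")
        if len(self.y) != n or len(self.z) != n:
            raise ValidationError(
                "axis sequences must have identical length: "
                f"x={len(self.x)} y={len(self.y)} z={len(self.z)}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def step(self) -> pd.Timedelta:
        return pd.Timedelta(seconds=1.0 / self.rate_hz)

    def times(self) -> pd.DatetimeIndex:
        """Timestamps implied by ``start + index / rate_hz``."""
        offsets = pd.to_timedelta(
            np.round(np.arange(self.n_samples) / self.rate_hz * 1e9).astype(
                np.int64
            ),
            unit="ns",
        )
        return self.start + offsets

    def missing_mask(self) -> np.ndarray:
        return ~(np.isfinite(self.x) & np.isfinite(self.y) & np.isfinite(self.z))


@dataclasses.dataclass
class OdbaSeries:
    """Per-sample ODBA aligned to its source trace, with provenance.

    ``hourly`` and ``daily`` aggregates are populated by
    :func:`noctograph.odba.aggregate` and carry NaN for periods failing the
    coverage policy.
    """

    animal_id: str
    start: pd.Timestamp
    rate_hz: float
    window_s: float
    per_sample: np.ndarray
    hourly: Optional[pd.Series] = None
    daily: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.start = _as_timestamp(self.start)
        self.per_sample = np.asarray(self.per_sample, dtype=float)
        finite = self.per_sample[np.isfinite(self.per_sample)]
        if finite.size and finite.min() < 0:
            raise ValidationError("ODBA values must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.per_sample)

    def times(self) -> pd.DatetimeIndex:
        offsets = pd.to_timedelta(
            np.round(np.arange(self.n_samples) / self.rate_hz * 1e9).astype(
                np.int64
            ),
            unit="ns",
        )
        return self.start + offsets

    def as_series(self) -> pd.Series:
        return pd.Series(self.per_sample, index=self.times(), name="odba_g")


@dataclasses.dataclass
class TwilightTable:
    """Per-date civil dawn and dusk times for one site.

    ``frame`` is indexed by normalized dates with columns ``civil_dawn`` and
    ``civil_dusk`` (naive local-standard timestamps).  ``site`` may be None
    when the table was read from a file that does not record it.
    """

    frame: pd.DataFrame
    site: Optional[object] = None  # twilight.Site; kept loose to avoid a cycle

    def __post_init__(self) -> None:
        required = {"civil_dawn", "civil_dusk"}
        if not required.issubset(self.frame.columns):
            raise ValidationError(f"twilight table needs columns {sorted(required)}")
        frame = self.frame.sort_index()
        if (frame["civil_dawn"] >= frame["civil_dusk"]).any():
            raise ValidationError("civil dawn must precede civil dusk on every date")
        # Night (dusk -> next dawn) plus day (dawn -> dusk) must tile 24 h.
        # The seasonal drift of dawn shifts the sum by a couple of minutes
        # per day at mid latitudes, so the tolerance is loose; it exists to
        # catch gross errors (wrong timezone, swapped dawn/dusk columns).
        dates = frame.index
        consecutive = dates[1:][(dates[1:] - dates[:-1]) == pd.Timedelta(days=1)]
        for d in consecutive:
            prev = d - pd.Timedelta(days=1)
            night = frame.loc[d, "civil_dawn"] - frame.loc[prev, "civil_dusk"]
            day = frame.loc[prev, "civil_dusk"] - frame.loc[prev, "civil_dawn"]
            total = night + day
            if abs(total - pd.Timedelta(hours=24)) > pd.Timedelta(minutes=5):
                raise ValidationError(
                    f"day+night around {prev.date()} is {total}, not 24 h +/- 5 min"
                )
        self.frame = frame

    def dawn(self, date) -> pd.Timestamp:
        return self.frame.loc[pd.Timestamp(date).normalize(), "civil_dawn"]

    def dusk(self, date) -> pd.Timestamp:
        return self.frame.loc[pd.Timestamp(date).normalize(), "civil_dusk"]


@dataclasses.dataclass
class ActivityDay:
    """One noon-to-noon animal-night and what the detector found in it.

    ``night_date`` is the date of the noon boundary opening the night; an
    offset at 05:00 therefore belongs to the *previous* calendar date's
    night.  Relative times follow the figure-caption convention: positive
    means the event occurred after its reference twilight.
    """

    animal_id: str
    night_date: pd.Timestamp
    onset: Optional[pd.Timestamp] = None
    offset: Optional[pd.Timestamp] = None
    duration_h: Optional[float] = None
    onset_rel_dusk_min: Optional[float] = None
    offset_rel_dawn_min: Optional[float] = None
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.night_date = pd.Timestamp(self.night_date).normalize()
        self.flags = frozenset(self.flags)
        if self.onset is not None and self.offset is not None:
            if self.onset >= self.offset:
                raise ValidationError(
                    f"onset {self.onset} must precede offset {self.offset}"
                )
        if self.duration_h is not None:
            if self.onset is None or self.offset is None:
                raise ValidationError("duration requires both onset and offset")
            if not 0 < self.duration_h < 24:
                raise ValidationError(
                    f"duration must lie in (0, 24) h, got {self.duration_h}"
                )


def activity_days_frame(days: Iterable[ActivityDay]) -> pd.DataFrame:
    rows = []
    for d in days:
        rows.append(
            {
                "animal_id": d.animal_id,
                "night_date": d.night_date,
                "onset": d.onset,
                "offset": d.offset,
                "duration_h": d.duration_h,
                "onset_rel_dusk_min": d.onset_rel_dusk_min,
                "offset_rel_dawn_min": d.offset_rel_dawn_min,
                "flags": ";".join(sorted(d.flags)),
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class DayRecord:
    """Model-ready calendar-day row joining activity and weather."""

    animal_id: str
    date: pd.Timestamp
    sex: str
    stage: str
    mean_daily_odba: float
    temp_c: Optional[float] = None
    wind_ms: Optional[float] = None
    precip_sqrt: Optional[float] = None
    snow_cat: Optional[str] = None

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date).normalize()
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.stage not in STAGES:
            raise ValidationError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.stage == "lactation" and self.sex != "female":
            raise ValidationError("lactation rows are female-only in this design")
        if self.precip_sqrt is not None and self.precip_sqrt < 0:
            raise ValidationError("precip_sqrt must be non-negative")
        if self.snow_cat is not None:
            if self.snow_cat not in SNOW_CATEGORIES:
                raise ValidationError(
                    f"snow_cat must be one of {SNOW_CATEGORIES}, got {self.snow_cat!r}"
                )
            if self.snow_cat == "ge8cm" and self.stage != "winter":
                raise ValidationError("snow cover >= 8 cm occurs only in winter rows")


def day_records_frame(records: Iterable[DayRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def night_of(times: pd.DatetimeIndex, boundary: dt.time = DAY_BOUNDARY) -> pd.DatetimeIndex:
    """Date of the noon-to-noon night each timestamp belongs to.

    A sample at or after ``boundary`` belongs to that calendar date's night;
    a sample before it belongs to the previous date's night.
    """
    shift = pd.Timedelta(hours=boundary.hour, minutes=boundary.minute)
    return (pd.DatetimeIndex(times) - shift).normalize()


def to_activity_days(
    series: "OdbaSeries | pd.DatetimeIndex",
    boundary: dt.time = DAY_BOUNDARY,
) -> "dict[pd.Timestamp, np.ndarray]":
    """Partition samples into noon-to-noon nights.

    Returns an ordered mapping from night date (the date of the opening
    boundary) to the integer positions of the samples in that night.  Every
    sample is assigned to exactly one night.
    """
    if isinstance(series, OdbaSeries):
        times = series.times()
    else:
        times = pd.DatetimeIndex(series)
    if len(times) == 0:
        raise ValidationError("cannot partition an empty series")
    labels = night_of(times, boundary)
    out: dict[pd.Timestamp, np.ndarray] = {}
    codes, uniques = pd.factorize(labels, sort=True)
    for i, night in enumerate(uniques):
        out[night] = np.flatnonzero(codes == i)
    return out
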