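"""Civil twilight from standard solar geometry.

Civil dawn/dusk are the times at which the geometric center of the sun
crosses 6 degrees below the horizon (zenith angle 96 deg).  The computation
follows the NOAA solar-calculator equations (low-precision Meeus series for
solar declination and the equation of time, plus hour-angle inversion),
which are accurate to well under a minute for the sun in the present era.
No refraction correction is applied: civil twilight is defined
geometrically.

Times are returned in fixed local standard time (``tz_offset_h`` hours from
UTC), matching the rest of the package.  A two-pass refinement evaluates
the solar series at the first-pass event time, which gives sub-minute
stability; the seed for the first pass is local solar noon.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math

import pandas as pd

from .core import TwilightTable, ValidationError

#: Solar zenith angle defining civil twilight, degrees.
CIVIL_ZENITH_DEG = 96.0

#: Latitude bound inside which civil twilight exists year-round.
MAX_ABS_LATITUDE = 66.5


class NoTwilightError(ValueError):
    """The sun does not cross -6 deg elevation on the requested date."""


@dataclasses.dataclass(frozen=True)
class Site:
    """Observer location: latitude deg N, longitude deg E, UTC offset h.

    Civil twilight exists on every date only for ``|latitude| < 66.5``;
    poleward of that, individual dates raise :class:`NoTwilightError`.
    """

    latitude: float
    longitude: float
    tz_offset_h: float

    def __post_init__(self) -> None:
        if not abs(self.latitude) < 90:
            raise ValidationError(f"latitude out of range: {self.latitude}")
        if not -180 <= self.longitude <= 180:
            raise ValidationError(f"longitude out of range: {self.longitude}")

    @property
    def twilight_guaranteed(self) -> bool:
        return abs(self.latitude) < MAX_ABS_LATITUDE


#: The study site: Flagstaff, Arizona (35d11'57"N 111d37'52"W, UTC-7).
FLAGSTAFF = Site(latitude=35.19917, longitude=-111.63111, tz_offset_h=-7.0)


def _julian_centuries(ts_utc: pd.Timestamp) -> float:
    return (ts_utc.to_julian_date() - 2451545.0) / 36525.0


def _solar_position(jc: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians) at jc."""
    rad = math.radians
    gmls = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    gmas = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eq_ctr = (
        math.sin(rad(gmas)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(rad(2 * gmas)) * (0.019993 - 0.000101 * jc)
        + math.sin(rad(3 * gmas)) * 0.000289
    )
    true_long = gmls + eq_ctr
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(rad(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - 0.001813 * jc))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(rad(omega))
    decl = math.asin(math.sin(rad(obliq)) * math.sin(rad(app_long)))
    var_y = math.tan(rad(obliq / 2.0)) ** 2
    eq_time = 4.0 * math.degrees(
        var_y * math.sin(2 * rad(gmls))
        - 2.0 * ecc * math.sin(rad(gmas))
        + 4.0 * ecc * var_y * math.sin(rad(gmas)) * math.cos(2 * rad(gmls))
        - 0.5 * var_y * var_y * math.sin(4 * rad(gmls))
        - 1.25 * ecc * ecc * math.sin(2 * rad(gmas))
    )
    return eq_time, decl


def _hour_angle_deg(latitude: float, decl: float, zenith_deg: float, date) -> float:
    lat = math.radians(latitude)
    cos_ha = (
        math.cos(math.radians(zenith_deg)) / (math.cos(lat) * math.cos(decl))
        - math.tan(lat) * math.tan(decl)
    )
    if cos_ha > 1.0:
        raise NoTwilightError(
            f"sun never rises to -6 deg elevation on {date} (polar night)"
        )
    if cos_ha < -1.0:
        raise NoTwilightError(
            f"sun never descends to -6 deg elevation on {date} (midnight sun)"
        )
    return math.degrees(math.acos(cos_ha))


def _event_minutes(site: Site, date: pd.Timestamp, rising: bool) -> float:
    """Local-standard minutes after midnight of the -6 deg crossing."""
    # Pass 1: evaluate the solar series at local solar noon.
    guess_min = 720.0 - 4.0 * site.longitude - 0.0 + site.tz_offset_h * 60.0
    for _ in range(2):
        ts_utc = (
            date
            + pd.Timedelta(minutes=guess_min)
            - pd.Timedelta(hours=site.tz_offset_h)
        )
        eq_time, decl = _solar_position(_julian_centuries(ts_utc))
        ha = _hour_angle_deg(site.latitude, decl, CIVIL_ZENITH_DEG, date.date())
        noon_min = 720.0 - 4.0 * site.longitude - eq_time + site.tz_offset_h * 60.0
        guess_min = noon_min - 4.0 * ha if rising else noon_min + 4.0 * ha
    return guess_min


def solar_noon(site: Site, date) -> pd.Timestamp:
    """Local solar noon (sun crossing the meridian), local standard time."""
    date = pd.Timestamp(date).normalize()
    ts_utc = date + pd.Timedelta(hours=12) - pd.Timedelta(hours=site.tz_offset_h)
    eq_time, _ = _solar_position(_julian_centuries(ts_utc))
    minutes = 720.0 - 4.0 * site.longitude - eq_time + site.tz_offset_h * 60.0
    return date + pd.Timedelta(minutes=minutes)


def civil_twilight(site: Site, date) -> dict:
    """Civil dawn and dusk for one date.

    Returns ``{"civil_dawn": Timestamp, "civil_dusk": Timestamp}`` in local
    standard time.  Raises :class:`NoTwilightError` when the sun never
    crosses -6 deg elevation that date.
    """
    date = pd.Timestamp(date).normalize()
    dawn = date + pd.Timedelta(minutes=_event_minutes(site, date, rising=True))
    dusk = date + pd.Timedelta(minutes=_event_minutes(site, date, rising=False))
    return {"civil_dawn": dawn.round("s"), "civil_dusk": dusk.round("s")}


def twilight_table(site: Site, start, end) -> TwilightTable:
    """Per-date civil dawn/dusk for an inclusive date range."""
    dates = pd.date_range(pd.Timestamp(start).normalize(), pd.Timestamp(end).normalize())
    rows = [civil_twilight(site, d) for d in dates]
    frame = pd.DataFrame(rows, index=dates)
    return TwilightTable(frame=frame, site=site)
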