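"""Independent solar-position oracle for twilight tests.

Implements the Michalsky (1988, Solar Energy 40:227-235) low-precision
solar ephemeris, an algorithm family distinct from the NOAA/Meeus series
used by the package, and locates civil-twilight crossings by brute-force
minute scanning refined with bisection.  Shares no code with
``noctograph.twilight``.
"""

from __future__ import annotations

import datetime as dt
import math


def solar_elevation_deg(lat: float, lon: float, when_utc: dt.datetime) -> float:
    """Geometric solar elevation (degrees) via Michalsky (1988)."""
    year = when_utc.year
    hour = (
        when_utc.hour
        + when_utc.minute / 60.0
        + when_utc.second / 3600.0
        + when_utc.microsecond / 3.6e9
    )
    day_of_year = when_utc.timetuple().tm_yday
    delta = year - 1949
    leap = delta // 4
    jd = 2432916.5 + delta * 365 + leap + day_of_year + hour / 24.0
    n = jd - 2451545.0

    mnlong = (280.460 + 0.9856474 * n) % 360.0
    mnanom = math.radians((357.528 + 0.9856003 * n) % 360.0)
    eclong = math.radians(
        (mnlong + 1.915 * math.sin(mnanom) + 0.020 * math.sin(2 * mnanom)) % 360.0
    )
    oblqec = math.radians(23.439 - 0.0000004 * n)

    num = math.cos(oblqec) * math.sin(eclong)
    den = math.cos(eclong)
    ra = math.atan2(num, den)  # right ascension, correct quadrant
    dec = math.asin(math.sin(oblqec) * math.sin(eclong))

    gmst = (6.697375 + 0.0657098242 * n + hour) % 24.0
    lmst = (gmst + lon / 15.0) % 24.0
    ha = math.radians(lmst * 15.0) - ra
    while ha > math.pi:
        ha -= 2 * math.pi
    while ha < -math.pi:
        ha += 2 * math.pi

    lat_r = math.radians(lat)
    el = math.asin(
        math.sin(dec) * math.sin(lat_r)
        + math.cos(dec) * math.cos(lat_r) * math.cos(ha)
    )
    return math.degrees(el)


def _elevation_local(lat, lon, tz_offset_hours, local: dt.datetime) -> float:
    utc = local - dt.timedelta(hours=tz_offset_hours)
    return solar_elevation_deg(lat, lon, utc)


def civil_twilight_oracle(lat, lon, tz_offset_hours, date):
    """(dawn, dusk) local datetimes at which elevation crosses -6 degrees.

    Minute-grid scan over the local day followed by bisection to <1 s.
    Returns None for a crossing that does not occur on that local day.
    """
    if isinstance(date, str):
        date = dt.date.fromisoformat(date)
    midnight = dt.datetime(date.year, date.month, date.day)
    target = -6.0

    grid = [midnight + dt.timedelta(minutes=m) for m in range(0, 24 * 60 + 1)]
    elev = [_elevation_local(lat, lon, tz_offset_hours, t) for t in grid]

    def bisect(t_lo, t_hi):
        for _ in range(40):
            mid = t_lo + (t_hi - t_lo) / 2
            if (_elevation_local(lat, lon, tz_offset_hours, t_lo) - target) * (
                _elevation_local(lat, lon, tz_offset_hours, mid) - target
            ) <= 0:
                t_hi = mid
            else:
                t_lo = mid
            if (t_hi - t_lo).total_seconds() < 0.5:
                break
        return t_lo + (t_hi - t_lo) / 2

    dawn = dusk = None
    for i in range(len(grid) - 1):
        lo, hi = elev[i] - target, elev[i + 1] - target
        if lo < 0 <= hi and dawn is None:  # upward crossing
            dawn = bisect(grid[i], grid[i + 1])
        if lo >= 0 > hi:  # downward crossing (keep the last one)
            dusk = bisect(grid[i], grid[i + 1])
    return dawn, dusk
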