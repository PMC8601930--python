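"""Independent ephemeris oracle for sunrise/sunset tests.

Implements the Astronomical Almanac's low-precision solar position (ecliptic
longitude -> right ascension/declination, Greenwich sidereal time -> hour
angle -> elevation) and finds rise/set as the minute-grid crossings of solar
elevation through -0.833 deg, with linear interpolation between grid points.

This is deliberately a different algorithm from the package's sunrise
equations (no equation of time, no hour-angle closed form), so agreement is a
genuine cross-check, good to well under a minute at mid-latitudes.
"""

from __future__ import annotations

import math
from datetime import date, datetime, timedelta, timezone

RISE_SET_ALTITUDE_DEG = -0.833


def _julian_day(t: datetime) -> float:
    t = t.astimezone(timezone.utc)
    y, m = t.year, t.month
    d = t.day + (t.hour + t.minute / 60.0 + t.second / 3600.0) / 24.0
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def solar_elevation_deg(t: datetime, lat_deg: float, lon_deg: float) -> float:
    """Apparent-free geometric solar elevation (degrees) at instant `t`."""
    n = _julian_day(t) - 2451545.0
    L = math.radians((280.460 + 0.9856474 * n) % 360.0)
    g = math.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = L + math.radians(1.915) * math.sin(g) + math.radians(0.020) * math.sin(2 * g)
    eps = math.radians(23.439 - 0.0000004 * n)
    ra = math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam))
    dec = math.asin(math.sin(eps) * math.sin(lam))
    gmst_deg = (280.46061837 + 360.98564736629 * n) % 360.0
    ha = math.radians(gmst_deg + lon_deg) - ra
    lat = math.radians(lat_deg)
    sin_el = math.sin(lat) * math.sin(dec) + math.cos(lat) * math.cos(dec) * math.cos(ha)
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_el))))


def rise_set_minutes(
    day: date, lat_deg: float, lon_deg: float, utc_offset_minutes: int
) -> tuple[float | None, float | None]:
    """(sunrise, sunset) as fractional minutes past local midnight of `day`,
    from a one-minute elevation scan; None if the sun never crosses."""
    tz = timezone(timedelta(minutes=utc_offset_minutes))
    midnight = datetime(day.year, day.month, day.day, tzinfo=tz)
    elev = [
        solar_elevation_deg(midnight + timedelta(minutes=m), lat_deg, lon_deg)
        - RISE_SET_ALTITUDE_DEG
        for m in range(0, 1441)
    ]
    sunrise = sunset = None
    for m in range(1440):
        a, b = elev[m], elev[m + 1]
        if a < 0.0 <= b and sunrise is None:
            sunrise = m + a / (a - b)
        if a >= 0.0 > b and sunset is None:
            sunset = m + a / (a - b)
    return sunrise, sunset
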