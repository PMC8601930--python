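"""Sunrise/sunset computation and the 15th-of-month anchor convention.

Sunrise and sunset are computed from the NOAA solar-calculator equations
(equation of time and solar declination from Julian-century polynomials and
the equation of center, hour angle at the standard rise/set zenith of
90.833 deg, which folds in atmospheric refraction (34') and the solar
semidiameter (16')).  Event times are refined by fixed-point iteration, so
accuracy is well under a minute across 1950-2100 at mid-latitudes — ample
for diel classification of camera-trap events.

All times are handled in a fixed local UTC offset supplied by the caller:
daylight-saving transitions are resolved upstream by storing every event
timestamp with its own offset and converting through UTC, so this module never
needs a tz database.

Diel classification in this pipeline does not use per-date solar times.
Instead each calendar month is anchored to the solar times of its 15th day
(:func:`anchor_solar_day`), so the day/night boundary is constant within a
month and tracks seasonal daylength change between months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta, timezone

from .errors import UnsupportedLocationError, ValidationError

RISE_SET_ZENITH_DEG = 90.833
#: Highest absolute latitude supported (polar day/night excluded).
MAX_ABS_LATITUDE_DEG = 66.0

__all__ = [
    "GeoPoint",
    "SolarDay",
    "solar_events",
    "anchor_solar_day",
    "RISE_SET_ZENITH_DEG",
]


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 geographic point in decimal degrees (east/north positive)."""

    latitude_deg: float
    longitude_deg: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise ValidationError(f"latitude {self.latitude_deg} outside [-90, 90]")
        if not -180.0 <= self.longitude_deg <= 180.0:
            raise ValidationError(f"longitude {self.longitude_deg} outside [-180, 180]")


@dataclass(frozen=True)
class SolarDay:
    """Sunrise and sunset for one calendar date at one location.

    The stored instants are unrounded (sub-second resolution); display code
    should round to whole minutes, but classification always compares against
    the unrounded clock times so the day/night boundary cannot drift with
    formatting.
    """

    date: date
    sunrise_local: datetime
    sunset_local: datetime
    utc_offset_minutes: int

    @property
    def daylength_minutes(self) -> float:
        return (self.sunset_local - self.sunrise_local).total_seconds() / 60.0

    @property
    def sunrise_clock_minutes(self) -> float:
        """Sunrise as fractional minutes past local midnight."""
        return _clock_minutes(self.sunrise_local)

    @property
    def sunset_clock_minutes(self) -> float:
        """Sunset as fractional minutes past local midnight."""
        return _clock_minutes(self.sunset_local)

    @property
    def night_length_minutes(self) -> float:
        """Minutes from this day's sunset to the next clock sunrise."""
        return 1440.0 - self.daylength_minutes

    def rounded(self) -> tuple[time, time]:
        """(sunrise, sunset) rounded to whole minutes, for display."""
        return (_round_to_minute(self.sunrise_local), _round_to_minute(self.sunset_local))


def _clock_minutes(t: datetime) -> float:
    return t.hour * 60.0 + t.minute + t.second / 60.0 + t.microsecond / 6e7


def _round_to_minute(t: datetime) -> time:
    t = t + timedelta(seconds=30)
    return time(t.hour, t.minute)


def _julian_day(day: date, utc_minutes: float) -> float:
    """Julian day at `utc_minutes` past UTC midnight of `day`."""
    y, m = day.year, day.month
    d = day.day + utc_minutes / 1440.0
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _eqtime_declination(day: date, utc_minutes: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians) at an
    instant, from the NOAA solar-calculator series (Julian centuries from
    J2000, geometric mean longitude/anomaly, equation of center, apparent
    longitude corrected for nutation, mean obliquity polynomial)."""
    T = (_julian_day(day, utc_minutes) - 2451545.0) / 36525.0
    L0 = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = math.radians(M)
    center = (
        math.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + math.sin(2 * Mr) * (0.019993 - 0.000101 * T)
        + math.sin(3 * Mr) * 0.000289
    )
    omega = math.radians(125.04 - 1934.136 * T)
    app_long = L0 + center - 0.00569 - 0.00478 * math.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))
    decl = math.asin(math.sin(eps) * math.sin(math.radians(app_long)))
    var_y = math.tan(eps / 2.0) ** 2
    L0r = math.radians(L0)
    eqtime = 4.0 * math.degrees(
        var_y * math.sin(2 * L0r)
        - 2.0 * e * math.sin(Mr)
        + 4.0 * e * var_y * math.sin(Mr) * math.cos(2 * L0r)
        - 0.5 * var_y**2 * math.sin(4 * L0r)
        - 1.25 * e**2 * math.sin(2 * Mr)
    )
    return eqtime, decl


def _hour_angle_deg(lat_rad: float, decl_rad: float) -> float:
    zen = math.radians(RISE_SET_ZENITH_DEG)
    cos_ha = (math.cos(zen) - math.sin(lat_rad) * math.sin(decl_rad)) / (
        math.cos(lat_rad) * math.cos(decl_rad)
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise UnsupportedLocationError(
            "sun does not cross the rise/set zenith on this date at this latitude"
        )
    return math.degrees(math.acos(cos_ha))


def _event_utc_minutes(day: date, point: GeoPoint, rise: bool) -> float:
    """Minutes past UTC midnight of `day` for sunrise (rise=True) or sunset.

    Fixed-point refinement: the first pass evaluates the equation of time and
    the declination at local solar noon, later passes at the current event
    estimate, which removes the ~1-minute drift of the single-pass formula.
    """
    lat = math.radians(point.latitude_deg)
    utc_minutes = 720.0 - 4.0 * point.longitude_deg  # local solar noon, first guess
    for _ in range(3):
        eqtime, decl = _eqtime_declination(day, utc_minutes)
        ha = _hour_angle_deg(lat, decl)
        if rise:
            utc_minutes = 720.0 - 4.0 * (point.longitude_deg + ha) - eqtime
        else:
            utc_minutes = 720.0 - 4.0 * (point.longitude_deg - ha) - eqtime
    return utc_minutes


def solar_events(day: date, point: GeoPoint, utc_offset_minutes: int) -> SolarDay:
    """Sunrise and sunset on `day` at `point`, expressed in a fixed UTC offset.

    Parameters
    ----------
    day
        Calendar date in the local offset; supported years 1950-2100.
    point
        Camera or site location.
    utc_offset_minutes
        Signed fixed offset of the local clock from UTC (e.g. -360 for CST).

    Raises
    ------
    UnsupportedLocationError
        For latitudes poleward of 66 deg, where polar day/night can occur.
    ValidationError
        For offsets beyond +/-14 h or dates outside 1950-2100.
    """
    if abs(point.latitude_deg) >= MAX_ABS_LATITUDE_DEG:
        raise UnsupportedLocationError(
            f"|latitude| >= {MAX_ABS_LATITUDE_DEG} deg not supported (polar day/night)"
        )
    if abs(utc_offset_minutes) > 14 * 60:
        raise ValidationError(f"UTC offset {utc_offset_minutes} min exceeds +/-14 h")
    if not 1950 <= day.year <= 2100:
        raise ValidationError(f"year {day.year} outside supported range 1950-2100")

    tz = timezone(timedelta(minutes=utc_offset_minutes))
    midnight_utc = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
    rise_utc = midnight_utc + timedelta(minutes=_event_utc_minutes(day, point, rise=True))
    set_utc = midnight_utc + timedelta(minutes=_event_utc_minutes(day, point, rise=False))
    return SolarDay(
        date=day,
        sunrise_local=rise_utc.astimezone(tz),
        sunset_local=set_utc.astimezone(tz),
        utc_offset_minutes=utc_offset_minutes,
    )


def anchor_solar_day(year: int, month: int, point: GeoPoint, utc_offset_minutes: int) -> SolarDay:
    """Solar times of the 15th day of (`year`, `month`) at `point`.

    Every detection in a month is classified day/night against this single
    anchor, so the diel boundary adapts to seasonal daylength month by month
    rather than day by day.
    """
    return solar_events(date(year, month, 15), point, utc_offset_minutes)
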