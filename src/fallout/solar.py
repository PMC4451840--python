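"""Apparent sunset from the NOAA solar calculator equations.

Implements the solar-position algorithm behind the NOAA ESRL sunrise/sunset
calculator (Meeus-style truncated series): apparent sunset is the UTC instant
at which the solar zenith angle reaches 90.833 degrees, the standard value
that folds in atmospheric refraction and the solar semidiameter.  Accuracy is
a minute or two at mid latitudes, which matches the precision of published
sunset tables.  Polar latitudes (|lat| >= 66 deg), where the sun may not set,
are rejected rather than approximated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

ZENITH_OFFICIAL_DEG = 90.833


@dataclass(frozen=True)
class SunsetSpec:
    """Apparent sunset for one civil date at one location."""

    date: date
    lon: float
    lat: float
    sunset_utc: datetime


def _julian_day(d: date) -> float:
    y, m = d.year, d.month
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d.day + b - 1524.5


def _solar_geometry(jc: float):
    """Equation of time (minutes) and solar declination (deg) at century jc."""
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mrad = math.radians(m)
    c = (
        math.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(omega))
    decl = math.degrees(math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long))))
    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    l0r = math.radians(l0)
    eq_time = 4.0 * math.degrees(
        var_y * math.sin(2 * l0r)
        - 2.0 * ecc * math.sin(mrad)
        + 4.0 * ecc * var_y * math.sin(mrad) * math.cos(2 * l0r)
        - 0.5 * var_y * var_y * math.sin(4 * l0r)
        - 1.25 * ecc * ecc * math.sin(2 * mrad)
    )
    return eq_time, decl


def _hour_angle_sunset_deg(lat: float, decl: float) -> float:
    latr, declr = math.radians(lat), math.radians(decl)
    cos_ha = (
        math.cos(math.radians(ZENITH_OFFICIAL_DEG)) / (math.cos(latr) * math.cos(declr))
        - math.tan(latr) * math.tan(declr)
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError("sun does not cross the sunset zenith on this date/latitude")
    return math.degrees(math.acos(cos_ha))


def apparent_sunset(d: date, lon: float, lat: float) -> SunsetSpec:
    """Apparent sunset (UTC) for civil date ``d`` at (lon, lat), WGS84 degrees.

    Longitude is positive east.  Raises for |lat| >= 66 deg (polar day/night
    handling is out of scope).
    """
    if abs(lat) >= 66.0:
        raise ValueError("polar latitudes (|lat| >= 66 deg) are unsupported")
    if abs(lon) > 180.0 or abs(lat) > 90.0:
        raise ValueError("invalid coordinates")
    jd = _julian_day(d)
    # iterate: evaluate the solar series at the current sunset estimate
    minutes_utc = 720.0 - 4.0 * lon
    for _ in range(3):
        jc = (jd + minutes_utc / 1440.0 - 2451545.0) / 36525.0
        eq_time, decl = _solar_geometry(jc)
        ha = _hour_angle_sunset_deg(lat, decl)
        solar_noon = 720.0 - 4.0 * lon - eq_time
        minutes_utc = solar_noon + 4.0 * ha
    base = datetime(d.year, d.month, d.day, tzinfo=timezone.utc)
    sunset = base + timedelta(minutes=minutes_utc)
    return SunsetSpec(date=d, lon=lon, lat=lat, sunset_utc=sunset)
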