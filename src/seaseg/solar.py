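"""Low-precision solar ephemeris.

Shared by the forward light simulator and the inverse (threshold) geolocation:
solar declination, equation of time, sun elevation, twilight crossing times and
day length.  Uses the classical low-precision series (geometric mean
longitude/anomaly, equation of centre, apparent obliquity — the algorithm
behind the NOAA solar calculator; accuracy well under 0.05 degrees and
0.1 min), far below the ~186 km error budget of light-level geolocation.

Conventions: all instants UTC; spherical Earth; angles in degrees at the API.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

_DateLike = Union[str, "pd.Timestamp", np.datetime64]


@dataclass(frozen=True)
class SolarCoordinates:
    """Solar declination and equation of time for one calendar date (at 12 UT)."""

    date_utc: pd.Timestamp
    declination_deg: float
    eot_min: float


def declination_eot(when) -> tuple[np.ndarray, np.ndarray]:
    """Declination (deg) and equation of time (min, apparent - mean) at instants."""
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(when, dtype="datetime64[s]")))
    jd = np.asarray(ts.to_julian_date(), dtype=float)
    t = (jd - 2451545.0) / 36525.0
    l0 = np.radians((280.46646 + 36000.76983 * t + 0.0003032 * t * t) % 360.0)
    m = np.radians(357.52911 + 35999.05029 * t - 0.0001537 * t * t)
    ecc = 0.016708634 - 0.000042037 * t - 0.0000001267 * t * t
    # equation of centre
    c = np.radians(
        (1.914602 - 0.004817 * t - 0.000014 * t * t) * np.sin(m)
        + (0.019993 - 0.000101 * t) * np.sin(2 * m)
        + 0.000289 * np.sin(3 * m)
    )
    true_lon = l0 + c
    omega = np.radians(125.04 - 1934.136 * t)
    app_lon = true_lon - np.radians(0.00569 + 0.00478 * np.sin(omega))
    eps0 = 23.0 + 26.0 / 60 + 21.448 / 3600 - (46.8150 * t + 0.00059 * t * t) / 3600
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))
    decl = np.degrees(np.arcsin(np.sin(eps) * np.sin(app_lon)))

    y = np.tan(eps / 2.0) ** 2
    eot_rad = (
        y * np.sin(2 * l0)
        - 2.0 * ecc * np.sin(m)
        + 4.0 * ecc * y * np.sin(m) * np.cos(2 * l0)
        - 0.5 * y * y * np.sin(4 * l0)
        - 1.25 * ecc * ecc * np.sin(2 * m)
    )
    eot = np.degrees(eot_rad) * 4.0
    return decl, eot


def solar_coordinates(date_utc: _DateLike) -> SolarCoordinates:
    """Declination and equation of time for a calendar date, evaluated at 12 UT."""
    day = pd.Timestamp(date_utc).normalize() + pd.Timedelta(hours=12)
    decl, eot = declination_eot(day)
    return SolarCoordinates(day.normalize(), float(decl[0]), float(eot[0]))


def sun_elevation(timestamp_utc, lon_deg, lat_deg) -> np.ndarray | float:
    """Solar elevation (deg) at UTC instants for a position (or arrays thereof).

    elevation = arcsin(sin phi sin delta + cos phi cos delta cos H) with the
    hour angle H derived from apparent local solar time (UTC + longitude offset
    + equation of time).
    """
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(timestamp_utc, dtype="datetime64[s]")))
    lon = np.atleast_1d(np.asarray(lon_deg, dtype=float))
    lat = np.atleast_1d(np.asarray(lat_deg, dtype=float))
    decl, eot = declination_eot(ts)
    utc_h = (
        np.asarray(ts.hour, dtype=float)
        + np.asarray(ts.minute, dtype=float) / 60.0
        + np.asarray(ts.second, dtype=float) / 3600.0
    )
    apparent_h = utc_h + lon / 15.0 + eot / 60.0
    hour_angle = np.radians(15.0 * (apparent_h - 12.0))
    phi = np.radians(lat)
    delta = np.radians(decl)
    s = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(hour_angle)
    elev = np.degrees(np.arcsin(np.clip(s, -1.0, 1.0)))
    if np.isscalar(timestamp_utc) or isinstance(timestamp_utc, (str, pd.Timestamp, np.datetime64)):
        if elev.size == 1:
            return float(elev[0])
    return elev


def hour_angle_deg(declination_deg, lat_deg, sun_angle_deg) -> np.ndarray:
    """Half the angular day arc: the hour angle at which the sun crosses
    ``sun_angle_deg``.  NaN where the sun never crosses (polar day/night)."""
    phi = np.radians(np.asarray(lat_deg, dtype=float))
    delta = np.radians(np.asarray(declination_deg, dtype=float))
    a = np.radians(np.asarray(sun_angle_deg, dtype=float))
    cos_h = (np.sin(a) - np.sin(phi) * np.sin(delta)) / (np.cos(phi) * np.cos(delta))
    out = np.where(np.abs(cos_h) <= 1.0, np.degrees(np.arccos(np.clip(cos_h, -1, 1))), np.nan)
    return out


def day_length_hours(declination_deg, lat_deg, sun_angle_deg) -> np.ndarray:
    """Day length (h) between threshold crossings; NaN for polar day/night."""
    return 2.0 * hour_angle_deg(declination_deg, lat_deg, sun_angle_deg) / 15.0


def day_length_and_twilights(
    date: _DateLike, lon_deg: float, lat_deg: float, sun_angle_deg: float = 0.0
):
    """Sunrise/sunset UTC instants and day length for one date and position.

    Returns ``(sunrise, sunset, day_length_h)``; all three are ``None``/NaN when
    the sun never crosses the threshold elevation (polar day or night).
    """
    day = pd.Timestamp(date).normalize()
    noon_guess = day + pd.Timedelta(hours=12)
    decl, eot = declination_eot(noon_guess)
    # apparent solar noon in UTC hours
    noon_utc_h = 12.0 - lon_deg / 15.0 - eot[0] / 60.0
    h0 = hour_angle_deg(decl[0], lat_deg, sun_angle_deg)
    if np.isnan(h0):
        return None, None, float("nan")
    half = h0 / 15.0
    sunrise = day + pd.Timedelta(hours=noon_utc_h - half)
    sunset = day + pd.Timedelta(hours=noon_utc_h + half)
    return sunrise, sunset, 2.0 * half
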