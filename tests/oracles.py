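"""Independent reference implementations used only as test oracles.

The solar oracle here is the low-precision Fourier ("fractional year")
expansion of declination and the equation of time — a different formulation
from the equation-of-centre series inside the package, so the two can
cross-validate.  The Fourier fit itself is good to roughly 0.3 degrees in
declination and one minute in the equation of time, which sets the
comparison tolerances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def solar_position_oracle(when) -> tuple[float, float]:
    """(declination_deg, equation_of_time_min) from the Fourier expansion."""
    ts = pd.Timestamp(when)
    doy = ts.dayofyear
    hour = ts.hour + ts.minute / 60.0
    days = 366.0 if ts.is_leap_year else 365.0
    g = 2.0 * np.pi / days * (doy - 1 + (hour - 12.0) / 24.0)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    eot = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    return float(np.degrees(decl)), float(eot)


def sun_elevation_oracle(when, lon_deg: float, lat_deg: float) -> float:
    """Solar elevation from the oracle ephemeris (no refraction)."""
    ts = pd.Timestamp(when)
    decl, eot = solar_position_oracle(ts)
    utc_h = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    hour_angle = np.radians(15.0 * (utc_h + lon_deg / 15.0 + eot / 60.0 - 12.0))
    phi, delta = np.radians(lat_deg), np.radians(decl)
    s = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(hour_angle)
    return float(np.degrees(np.arcsin(np.clip(s, -1, 1))))


# Almanac anchor facts (well-known annual extremes of the equation of time,
# apparent minus mean solar time): around 11 Feb the sun runs ~14.2 min slow,
# around 3 Nov ~16.4 min fast; near 15 Apr / 13 Jun / 1 Sep / 25 Dec the
# equation of time crosses zero.
EOT_EXTREMES = [("2010-02-11", -14.2), ("2010-11-03", 16.4)]
EOT_ZERO_DATES = ["2010-04-15", "2010-06-13", "2010-09-01", "2010-12-25"]
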