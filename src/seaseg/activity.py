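"""Immersion-logger activity and the Night Flight Index (NFI).

Immersion loggers sample saltwater conductivity every 3 s and report, per
aligned 10-min bin, the count of wet samples (0-200).  Dry time is read as
flight, wet time as sitting on the water, so the dry fraction of a bin,
(200 - wet)/200, is the time spent flying.

NFI for a day = (p_fly_dark - p_fly_light) / max(p_fly_dark, p_fly_light),
bounded in [-1, 1]: +1 means flight exclusively in darkness, -1 exclusively
in daylight, 0 no diel preference.  Because moonlight modulates nocturnal
activity, the per-bird summary is the mean daily NFI over one complete
synodic lunar cycle inside the nonbreeding period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import solar

WET_MAX = 200

SYNODIC_DAYS = 29.530588
# reference new moon: 2000-01-06 18:14 UTC
_NEW_MOON_EPOCH = pd.Timestamp("2000-01-06 18:14:00")


@dataclass(frozen=True)
class DailyActivity:
    date: pd.Timestamp
    p_fly_dark: float
    p_fly_light: float
    nfi: float


class MissingClassError(ValueError):
    """A day lacks dark bins or light bins entirely."""


class InsufficientCoverageError(ValueError):
    pass


def lunar_phase(when) -> np.ndarray:
    """Synodic phase in [0, 1): 0 = new moon (29.53-day cycle, fixed anchor)."""
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(when, dtype="datetime64[s]")))
    days = (ts - _NEW_MOON_EPOCH).total_seconds() / 86400.0
    return np.asarray(days % SYNODIC_DAYS) / SYNODIC_DAYS


def classify_light_dark(
    immersion: pd.DataFrame,
    lon,
    lat,
    sun_angle_deg: float = -4.5,
) -> pd.DataFrame:
    """Label each 10-min bin dark or light at the bird's estimated position.

    ``immersion`` needs columns ``timestamp`` (bin start, UTC) and ``wet``.
    ``lon``/``lat`` may be scalars or per-bin arrays (interpolated positions).
    A bin is dark when the sun at the bin midpoint sits below the calibrated
    twilight elevation, keeping the day/night definition consistent with the
    geolocation chain.  Adds a boolean ``dark`` column.
    """
    out = immersion.copy()
    mid = pd.DatetimeIndex(out["timestamp"]) + pd.Timedelta(minutes=5)
    elev = solar.sun_elevation(mid.values, lon, lat)
    out["dark"] = np.asarray(elev) < sun_angle_deg
    return out


def daily_nfi(day_bins: pd.DataFrame) -> DailyActivity:
    """Night Flight Index of one day of dark/light-labelled immersion bins."""
    dark = day_bins.loc[day_bins["dark"]]
    light = day_bins.loc[~day_bins["dark"]]
    if len(dark) == 0 or len(light) == 0:
        raise MissingClassError("day needs at least one dark and one light bin")
    p_dark = float((WET_MAX - dark["wet"]).sum() / (WET_MAX * len(dark)))
    p_light = float((WET_MAX - light["wet"]).sum() / (WET_MAX * len(light)))
    top = max(p_dark, p_light)
    nfi = 0.0 if top == 0.0 else (p_dark - p_light) / top
    date = pd.Timestamp(day_bins["timestamp"].iloc[0]).normalize()
    return DailyActivity(date, p_dark, p_light, nfi)


def daily_activity_table(labelled: pd.DataFrame) -> pd.DataFrame:
    """Per-day NFI table from a labelled immersion series.

    Days without both classes (polar-like edge cases) are skipped.
    """
    rows = []
    for date, grp in labelled.groupby(pd.DatetimeIndex(labelled["timestamp"]).normalize()):
        try:
            d = daily_nfi(grp)
        except MissingClassError:
            continue
        rows.append({"date": d.date, "p_fly_dark": d.p_fly_dark,
                     "p_fly_light": d.p_fly_light, "nfi": d.nfi})
    return pd.DataFrame(rows)


def mean_nfi_lunar_window(
    daily: pd.DataFrame,
    nonbreeding_interval: Tuple,
    window_days: int = 28,
) -> Tuple[float, Tuple[pd.Timestamp, pd.Timestamp]]:
    """Mean daily NFI over the first full lunar cycle in the nonbreeding period.

    The window starts at the first new moon (synodic phase ~0) such that the
    whole ``window_days`` span lies inside ``nonbreeding_interval`` and every
    day in it has an NFI value.  Returns ``(mean_nfi, (start, end))``.
    """
    t0 = pd.Timestamp(nonbreeding_interval[0]).normalize()
    t1 = pd.Timestamp(nonbreeding_interval[1]).normalize()
    if (t1 - t0).days < window_days:
        raise InsufficientCoverageError(
            f"nonbreeding interval shorter than {window_days} days"
        )
    avail = set(pd.DatetimeIndex(daily["date"]).normalize())
    # first new moon at or after t0
    phase0 = float(lunar_phase(t0)[0])
    offset = (1.0 - phase0) % 1.0 * SYNODIC_DAYS
    start = t0 + pd.Timedelta(days=float(np.ceil(offset)))
    while start + pd.Timedelta(days=window_days - 1) <= t1:
        days = pd.date_range(start, periods=window_days, freq="D")
        if all(d in avail for d in days):
            sel = daily.loc[pd.DatetimeIndex(daily["date"]).normalize().isin(days)]
            return float(sel["nfi"].mean()), (days[0], days[-1])
        start += pd.Timedelta(days=float(np.round(SYNODIC_DAYS)))
    # fall back: no complete new-moon-anchored window with full coverage
    raise InsufficientCoverageError(
        "no complete lunar-cycle window with daily NFI coverage inside the interval"
    )
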