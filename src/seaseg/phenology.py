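"""Migration phenology: event detection and per-bird-cycle schedules.

Events are read off the smoothed track with explicit, configurable rules
standing in for the visual inspection traditionally used with geolocator
tracks: a departure is the first day lying further than ``radius_km`` from
the median of the previous ``window_days`` days *and* followed by rapid
directional movement; an arrival is the first day whose next
``window_days`` days stay clustered within ``radius_km`` of their own
median.  Inside equinox masks (no latitude) the same rules run on longitude
alone, converted to km at the latitude of the nearest resolved fix.

A phenology cycle runs 1 July -> 30 June so austral wintering stays within
one cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .activity import classify_light_dark
from .geolocation import Track
from .space_use import great_circle_km, recenter_lons

KM_PER_DEG = 111.195  # great-circle km per degree at the equator (R=6371)


@dataclass
class MigrationSchedule:
    bird_id: str
    cycle_year: int
    departure_colony: Optional[pd.Timestamp] = None
    arrival_wintering: Optional[pd.Timestamp] = None
    departure_wintering: Optional[pd.Timestamp] = None
    arrival_colony: Optional[pd.Timestamp] = None
    migratory: bool = True

    @property
    def transit_out_days(self) -> Optional[int]:
        if self.departure_colony is None or self.arrival_wintering is None:
            return None
        return int((self.arrival_wintering - self.departure_colony).days)

    @property
    def days_in_area(self) -> Optional[int]:
        if self.arrival_wintering is None or self.departure_wintering is None:
            return None
        return int((self.departure_wintering - self.arrival_wintering).days)

    @property
    def transit_return_days(self) -> Optional[int]:
        if self.departure_wintering is None or self.arrival_colony is None:
            return None
        return int((self.arrival_colony - self.departure_wintering).days)

    @property
    def total_nonbreeding_days(self) -> Optional[int]:
        if self.departure_colony is None or self.arrival_colony is None:
            return None
        return int((self.arrival_colony - self.departure_colony).days)


def cycle_start(cycle_year: int) -> pd.Timestamp:
    return pd.Timestamp(f"{cycle_year}-07-01")


def daily_positions(track: Track) -> pd.DataFrame:
    """Collapse twice-daily estimates to one position per date.

    Longitudes are averaged on the circle (antimeridian-safe); masked
    latitudes stay missing.
    """
    pos = track.positions
    rows = []
    for date, grp in pos.groupby(pd.DatetimeIndex(pos["date"]).normalize()):
        lon = grp["lon"].to_numpy(dtype=float)
        lon = lon[np.isfinite(lon)]
        lat = grp["lat"].to_numpy(dtype=float)
        lat = lat[np.isfinite(lat)]
        if len(lon) == 0:
            continue
        shifted, _ = recenter_lons(lon)
        mlon = (np.mean(shifted) + 180.0) % 360.0 - 180.0
        rows.append({"date": date, "lon": float(mlon),
                     "lat": float(np.mean(lat)) if len(lat) else np.nan})
    return pd.DataFrame(rows).sort_values("date").reset_index(drop=True)


def _pairwise_km(lon1, lat1, lon2, lat2, lat_ref):
    """Distance in km; longitude-only (scaled at lat_ref) when a latitude is missing."""
    if np.isfinite(lat1) and np.isfinite(lat2):
        return great_circle_km(lon1, lat1, lon2, lat2)
    dlon = abs((lon1 - lon2 + 180.0) % 360.0 - 180.0)
    return dlon * KM_PER_DEG * np.cos(np.radians(lat_ref))


def _window_center(day_rows: pd.DataFrame) -> Tuple[float, float, float]:
    """Median lon/lat of a window plus a reference latitude for lon-only distances."""
    lon = day_rows["lon"].to_numpy(dtype=float)
    lat = day_rows["lat"].to_numpy(dtype=float)
    shifted, _ = recenter_lons(lon)
    mlon = (np.median(shifted) + 180.0) % 360.0 - 180.0
    finite = lat[np.isfinite(lat)]
    mlat = float(np.median(finite)) if len(finite) else np.nan
    lat_ref = mlat if np.isfinite(mlat) else 0.0
    return float(mlon), mlat, lat_ref


class TransitionNotFound(Exception):
    pass


def detect_transition(
    track: Track,
    direction: str,
    window_days: int = 10,
    radius_km: float = 500.0,
    speed_km_day: float = 200.0,
    start_date=None,
) -> pd.Timestamp:
    """First date satisfying the departure or arrival rule (see module docs).

    ``start_date`` restricts the search to dates at or after it.  Raises
    :class:`TransitionNotFound` when no date qualifies.
    """
    daily = daily_positions(track)
    if start_date is not None:
        daily = daily.loc[pd.DatetimeIndex(daily["date"]) >= pd.Timestamp(start_date)]
        daily = daily.reset_index(drop=True)
    n = len(daily)
    if n < window_days + 3:
        raise TransitionNotFound(f"need >= {window_days + 3} daily positions, got {n}")
    lon = daily["lon"].to_numpy(dtype=float)
    lat = daily["lat"].to_numpy(dtype=float)
    dates = pd.DatetimeIndex(daily["date"])

    if direction == "departure":
        for i in range(window_days, n - 2):
            win = daily.iloc[i - window_days:i]
            mlon, mlat, lat_ref = _window_center(win)
            # the bird must leave the cluster *and stay out* (robust to the
            # ~186 km position noise of geolocation) ...
            out = all(
                _pairwise_km(lon[k], lat[k], mlon, mlat, lat_ref) > radius_km
                for k in range(i, min(i + 3, n))
            )
            if not out:
                continue
            # ... while moving rapidly and directionally away
            j = min(i + 2, n - 1)
            disp = _pairwise_km(lon[i], lat[i], lon[j], lat[j], lat_ref)
            span = max((dates[j] - dates[i]).days, 1)
            if disp / span > speed_km_day:
                return dates[i]
        raise TransitionNotFound("no departure satisfied the cluster+speed rule")
    elif direction == "arrival":
        for i in range(n - window_days + 1):
            win = daily.iloc[i:i + window_days]
            mlon, mlat, lat_ref = _window_center(win)
            # the arrival day itself must sit in the cluster, and one stray
            # fix elsewhere in the window is tolerated: at the ~186 km error
            # level a single excursion beyond the radius is routine and must
            # not postpone a genuine arrival
            dists = [_pairwise_km(lon[k], lat[k], mlon, mlat, lat_ref)
                     for k in range(i, i + window_days)]
            if dists[0] <= radius_km and sum(d > radius_km for d in dists) <= 1:
                return dates[i]
        raise TransitionNotFound("no arrival cluster found")
    raise ValueError(f"direction must be 'departure' or 'arrival', got {direction!r}")


def colony_arrival_from_dry(
    immersion: pd.DataFrame,
    lon: float,
    lat: float,
    sun_angle_deg: float = -4.5,
    start_date=None,
) -> pd.Timestamp:
    """First date whose entire dark period has zero wet counts (bird at the
    colony all night).  The night between sunset of day d and sunrise of day
    d+1 is attributed to day d.  A single wet bin rejects the night.
    """
    lab = classify_light_dark(immersion, lon, lat, sun_angle_deg)
    if start_date is not None:
        lab = lab.loc[pd.DatetimeIndex(lab["timestamp"]) >= pd.Timestamp(start_date)]
    lab = lab.reset_index(drop=True)
    dark = lab["dark"].to_numpy(dtype=bool)
    if not dark.any():
        raise TransitionNotFound("no dark bins in immersion series")
    # contiguous runs of dark bins = nights
    edges = np.nonzero(np.diff(dark.astype(int)))[0]
    starts = [0] if dark[0] else []
    starts += [e + 1 for e in edges if dark[e + 1]]
    ends = [e for e in edges if dark[e]]
    if dark[-1]:
        ends.append(len(dark) - 1)
    ts = pd.DatetimeIndex(lab["timestamp"])
    wet = lab["wet"].to_numpy()
    first = True
    for s, e in zip(starts, ends):
        if first and s == 0:
            first = False
            continue  # truncated first night: coverage unknown
        if e == len(dark) - 1:
            break  # truncated last night
        if np.all(wet[s:e + 1] == 0):
            night_start = ts[s]
            return (night_start - pd.Timedelta(hours=12)).normalize() \
                if night_start.hour < 12 else night_start.normalize()
    raise TransitionNotFound("no all-dry night found")


def classify_migratory(
    wintering_centroid: Tuple[float, float],
    colony: Tuple[float, float],
    resident_radius_km: float = 1000.0,
) -> bool:
    """Migratory iff the wintering centroid sits strictly beyond
    ``resident_radius_km`` of the colony (great-circle)."""
    d = great_circle_km(wintering_centroid[0], wintering_centroid[1], colony[0], colony[1])
    return bool(d > resident_radius_km)


def build_schedule(
    track: Track,
    immersion: Optional[pd.DataFrame] = None,
    cycle_year: Optional[int] = None,
    window_days: int = 10,
    radius_km: float = 500.0,
    speed_km_day: float = 200.0,
    resident_radius_km: float = 1000.0,
    min_residence_days: int = 30,
    sun_angle_deg: float = -4.5,
) -> MigrationSchedule:
    """Assemble the four phenology dates and the migratory flag for one cycle.

    For nonmigratory birds only the colony-arrival date (from the all-dry
    night rule when immersion data are supplied) is populated.
    """
    daily = daily_positions(track)
    if cycle_year is None:
        first = pd.Timestamp(daily["date"].iloc[0])
        cycle_year = first.year if first.month >= 7 else first.year - 1
    sched = MigrationSchedule(track.bird_id, cycle_year)

    try:
        dep = detect_transition(track, "departure", window_days, radius_km, speed_km_day)
    except TransitionNotFound:
        dep = None
    if dep is None:
        sched.migratory = False
    else:
        sched.departure_colony = dep
        try:
            arr_w = detect_transition(
                track, "arrival", window_days, radius_km, speed_km_day,
                start_date=dep + pd.Timedelta(days=2),
            )
            sched.arrival_wintering = arr_w
        except TransitionNotFound:
            arr_w = None
        if arr_w is not None:
            # wintering centroid over the residence window
            sel = daily.loc[(pd.DatetimeIndex(daily["date"]) >= arr_w)]
            res = sel.iloc[: max(min_residence_days, 1)]
            mlon, mlat, _ = _window_center(res)
            if np.isfinite(mlat):
                sched.migratory = classify_migratory(
                    (mlon, mlat), track.colony, resident_radius_km
                )
            try:
                sched.departure_wintering = detect_transition(
                    track, "departure", window_days, radius_km, speed_km_day,
                    start_date=arr_w + pd.Timedelta(days=min_residence_days),
                )
            except TransitionNotFound:
                pass

    if not sched.migratory:
        sched.departure_colony = None
        sched.arrival_wintering = None
        sched.departure_wintering = None

    arr_col = None
    if immersion is not None:
        start = sched.departure_wintering or (
            cycle_start(cycle_year) + pd.Timedelta(days=200)
        )
        try:
            arr_col = colony_arrival_from_dry(
                immersion, track.colony[0], track.colony[1], sun_angle_deg,
                start_date=start,
            )
        except TransitionNotFound:
            arr_col = None
    if arr_col is None and sched.departure_wintering is not None:
        try:
            arr_col = detect_transition(
                track, "arrival", window_days, radius_km, speed_km_day,
                start_date=sched.departure_wintering + pd.Timedelta(days=2),
            )
        except TransitionNotFound:
            arr_col = None
    sched.arrival_colony = arr_col
    return sched


def schedule_table(schedules) -> pd.DataFrame:
    """Tidy one-row-per-bird-cycle table of dates and durations."""
    rows = []
    for s in schedules:
        rows.append(
            {
                "bird_id": s.bird_id,
                "cycle_year": s.cycle_year,
                "migratory": s.migratory,
                "departure_colony": s.departure_colony,
                "arrival_wintering": s.arrival_wintering,
                "departure_wintering": s.departure_wintering,
                "arrival_colony": s.arrival_colony,
                "transit_out_days": s.transit_out_days,
                "days_in_area": s.days_in_area,
                "transit_return_days": s.transit_return_days,
                "total_nonbreeding_days": s.total_nonbreeding_days,
            }
        )
    return pd.DataFrame(rows)
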