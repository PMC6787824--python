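"""Threshold light-level geolocation.

The classic chain for archival geolocators: detect twilights as threshold
crossings of the clipped light curve, calibrate the effective sun elevation
angle at a known site, invert twilight pairs to twice-daily positions
(longitude from the timing of local midday/midnight, latitude from day/night
length), mask latitudes around the equinoxes, remove speed outliers and apply
the conventional double smoothing.

Positions are handled as pandas DataFrames with columns
``date, half, timestamp, lon, lat, interference, lat_unresolved,
equinox_masked`` — one row per AM (sunrise->sunset) or PM (sunset->sunrise)
twilight pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import solar
from .space_use import great_circle_km

log = logging.getLogger(__name__)

LIGHT_MAX_DEFAULT = 64
LIGHT_THRESHOLD_DEFAULT = 20.0


@dataclass(frozen=True)
class CalibrationResult:
    sun_angle_deg: float
    residual_km: float


@dataclass
class Track:
    """One bird deployment: metadata plus ordered twice-daily position estimates."""

    bird_id: str
    sex: str
    species: str
    colony: Tuple[float, float]  # (lon, lat)
    positions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def copy(self) -> "Track":
        return Track(self.bird_id, self.sex, self.species, self.colony,
                     self.positions.copy())


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# twilight detection


def detect_twilights(
    light: pd.DataFrame,
    threshold: float = LIGHT_THRESHOLD_DEFAULT,
    guard_window_min: float = 30.0,
) -> pd.DataFrame:
    """Find sunrise/sunset threshold crossings in a light series.

    ``light`` needs columns ``timestamp`` (UTC) and ``light``.  An upward
    crossing of ``threshold`` is a sunrise, a downward crossing a sunset; the
    crossing instant is linearly interpolated between the bracketing samples.
    Events with another crossing within ``guard_window_min`` minutes are
    flagged ``interference`` (shading/artificial light near twilight).

    Because loggers sample light every 60 s and store the *maximum* over each
    recording interval stamped at the bin start, a rising light curve is
    effectively sampled at the last 60-s sample of the bin: sunrise crossings
    are therefore shifted late by (interval - 60 s) to undo that bias (falling
    light is effectively sampled at the bin start, so sunsets need no
    correction).

    Returns a DataFrame ``timestamp, kind, interference``.
    """
    ts = pd.DatetimeIndex(light["timestamp"])
    lv = np.asarray(light["light"], dtype=float)
    if len(lv) < 2:
        return pd.DataFrame(columns=["timestamp", "kind", "interference"])
    above = lv >= threshold
    change = np.nonzero(above[1:] != above[:-1])[0]
    if change.size == 0:
        log.warning("light series never crosses threshold %.1f", threshold)
        return pd.DataFrame(columns=["timestamp", "kind", "interference"])
    t0 = ts[change].asi8.astype(float)
    t1 = ts[change + 1].asi8.astype(float)
    frac = (threshold - lv[change]) / (lv[change + 1] - lv[change])
    cross_ns = t0 + frac * (t1 - t0)
    kind = np.where(above[change + 1], "sunrise", "sunset")
    shift_ns = max(float(np.median(np.diff(ts.asi8))) - 60e9, 0.0)
    cross_ns = cross_ns + np.where(kind == "sunrise", shift_ns, 0.0)
    cross = pd.DatetimeIndex(cross_ns.astype("int64").view("M8[ns]"))
    # interference: another crossing within the guard window on either side
    guard_ns = guard_window_min * 60e9
    gaps = np.diff(cross_ns)
    close = np.zeros(len(cross_ns), dtype=bool)
    close[:-1] |= gaps <= guard_ns
    close[1:] |= gaps <= guard_ns
    return pd.DataFrame({"timestamp": cross, "kind": kind, "interference": close})


def drop_interference(twilights: pd.DataFrame) -> pd.DataFrame:
    """Remove interference-flagged events and any non-alternating leftovers."""
    tw = twilights.loc[~twilights["interference"]].reset_index(drop=True)
    keep = np.ones(len(tw), dtype=bool)
    last_kind = None
    for i, k in enumerate(tw["kind"]):
        if k == last_kind:
            keep[i] = False  # duplicated kind after removals: keep the first
        else:
            last_kind = k
    return tw.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# position inversion


def _solve_latitude(delta_deg, sun_angle_deg, day_len_h, lat_lo, lat_hi, tol=0.01):
    """Vectorized bracket-scan + bisection for the latitude whose day length
    matches the observed twilight interval.

    Day length is not monotone in latitude all the way to the poles (it
    collapses at the polar-night limit), so the residual is first scanned on
    a 1-degree grid from the equator side of [lat_lo, lat_hi]; the first
    bracketing interval is then bisected to ``tol``.  NaN where no bracket
    exists (no latitude reproduces the observed day length).
    """
    delta = np.asarray(delta_deg, dtype=float)
    dl = np.asarray(day_len_h, dtype=float)

    def resid(phi):
        pred = solar.day_length_hours(delta, phi, sun_angle_deg)
        # saturate polar day/night so the residual keeps a usable sign
        pred = np.where(np.isnan(pred),
                        np.where(np.sin(np.radians(phi)) * np.sin(np.radians(delta)) > 0,
                                 24.0, 0.0),
                        pred)
        return pred - dl

    # scan from the end nearer the equator outward
    if abs(lat_lo) <= abs(lat_hi):
        grid = np.arange(lat_lo, lat_hi + 1.0, 1.0)
    else:
        grid = np.arange(lat_hi, lat_lo - 1.0, -1.0)
    grid = np.clip(grid, min(lat_lo, lat_hi), max(lat_lo, lat_hi))
    res = np.stack([resid(np.full_like(dl, g)) for g in grid])  # (n_grid, n)
    sign_change = np.sign(res[:-1]) * np.sign(res[1:]) <= 0
    first = np.argmax(sign_change, axis=0)
    ok = sign_change[first, np.arange(res.shape[1])]
    lo = grid[first].astype(float)
    hi = grid[first + 1].astype(float)
    flo = res[first, np.arange(res.shape[1])]
    for _ in range(12):  # 1 deg / 2^12 << 0.01 deg
        mid = 0.5 * (lo + hi)
        fm = resid(mid)
        take_lo = np.sign(fm) == np.sign(flo)
        lo = np.where(take_lo, mid, lo)
        flo = np.where(take_lo, fm, flo)
        hi = np.where(take_lo, hi, mid)
    out = 0.5 * (lo + hi)
    return np.where(ok, out, np.nan)


def positions_from_twilights(
    twilights: pd.DataFrame,
    sun_angle_deg: float,
    ambiguous_declination_deg: float = 1.5,
) -> pd.DataFrame:
    """Invert consecutive twilight pairs into twice-daily positions.

    Longitude comes from the apparent-solar-midday (AM pairs) or midnight
    (PM pairs) timing relative to UTC, corrected for the equation of time;
    latitude from the day (or night) length via bisection on [-89, 89].
    Near the equinoxes (|declination| below ``ambiguous_declination_deg``)
    the hemisphere is ambiguous: both branches are solved, the one nearer the
    closest unambiguous latitude is kept and the row is flagged
    ``lat_unresolved``.
    """
    tw = twilights.reset_index(drop=True)
    if len(tw) < 2:
        return pd.DataFrame(columns=["date", "half", "timestamp", "lon", "lat",
                                     "interference", "lat_unresolved", "equinox_masked"])
    t = pd.DatetimeIndex(tw["timestamp"]).asi8.astype(float)
    kinds = np.asarray(tw["kind"])
    interf = np.asarray(tw["interference"], dtype=bool)

    i0 = np.arange(len(tw) - 1)
    valid = kinds[i0] != kinds[i0 + 1]
    # drop physically implausible pairs (an event was lost in between):
    # a day or night arc must last between 2 and 22 hours
    span_h = (t[i0 + 1] - t[i0]) / 3.6e12
    valid &= (span_h > 2.0) & (span_h < 22.0)
    i0 = i0[valid]
    mid_ns = 0.5 * (t[i0] + t[i0 + 1])
    mid = pd.DatetimeIndex(mid_ns.astype("int64").view("M8[ns]"))
    interval_h = (t[i0 + 1] - t[i0]) / 3.6e12
    is_am = kinds[i0] == "sunrise"
    day_len = np.where(is_am, interval_h, 24.0 - interval_h)

    decl, eot = solar.declination_eot(mid)
    utc_h = (mid_ns - pd.DatetimeIndex(mid.normalize()).asi8.astype(float)) / 3.6e12
    target_h = np.where(is_am, 12.0, 24.0)
    # apparent local time = UTC + lon/15 + eot/60 must equal 12 (noon) or 24/0
    lon = 15.0 * (target_h - utc_h - eot / 60.0)
    lon = (lon + 180.0) % 360.0 - 180.0

    lat_n = _solve_latitude(decl, sun_angle_deg, day_len, 0.0, 89.0)
    lat_s = _solve_latitude(decl, sun_angle_deg, day_len, -89.0, 0.0)
    ambiguous = np.abs(decl) < ambiguous_declination_deg
    # default: the branch matching the sign of the declination response
    lat = np.where(np.isnan(lat_n), lat_s, lat_n)
    both = ~np.isnan(lat_n) & ~np.isnan(lat_s)
    # where both branches solve, prefer the one away from zero only if unique;
    # ambiguity resolved below against neighbours
    unresolved = ambiguous | (both & (np.abs(lat_n + lat_s) < 2.0)) | np.isnan(lat)

    out = pd.DataFrame(
        {
            "date": mid.normalize(),
            "half": np.where(is_am, "AM", "PM"),
            "timestamp": mid,
            "lon": lon,
            "lat": lat,
            "lat_north": lat_n,
            "lat_south": lat_s,
            "interference": interf[i0] | interf[i0 + 1],
            "lat_unresolved": unresolved,
            "equinox_masked": False,
        }
    )
    # nearest-in-time unambiguous latitude picks the hemisphere for flagged rows
    good = out.loc[~out["lat_unresolved"] & out["lat"].notna()]
    if len(good):
        ref_t = pd.DatetimeIndex(good["timestamp"]).asi8
        ref_lat = np.asarray(good["lat"], dtype=float)
        for i in out.index[out["lat_unresolved"]]:
            j = np.argmin(np.abs(ref_t - out.at[i, "timestamp"].value))
            ln, ls = out.at[i, "lat_north"], out.at[i, "lat_south"]
            cand = [v for v in (ln, ls) if np.isfinite(v)]
            if cand:
                out.at[i, "lat"] = min(cand, key=lambda v: abs(v - ref_lat[j]))
    return out.drop(columns=["lat_north", "lat_south"])


# ---------------------------------------------------------------------------
# calibration


def calibrate_sun_angle(
    twilights: pd.DataFrame,
    known_site: Tuple[float, float],
    calibration_window: Optional[Tuple] = None,
    angle_grid: Optional[np.ndarray] = None,
) -> CalibrationResult:
    """Grid-search the sun elevation angle minimising the median great-circle
    error of inverted positions at a known site (the colony, during the
    pre-deployment week).  Warns when the optimum falls outside the
    empirically usual [-6, -3] degree band.
    """
    tw = twilights
    if calibration_window is not None:
        t0, t1 = (pd.Timestamp(calibration_window[0]), pd.Timestamp(calibration_window[1]))
        sel = (pd.DatetimeIndex(tw["timestamp"]) >= t0) & (pd.DatetimeIndex(tw["timestamp"]) <= t1)
        tw = tw.loc[sel].reset_index(drop=True)
    n_days = pd.DatetimeIndex(tw["timestamp"]).normalize().nunique()
    if n_days < 5:
        raise InsufficientDataError(
            f"calibration needs >= 5 complete days of twilights, got {n_days}"
        )
    if angle_grid is None:
        angle_grid = np.arange(-9.0, 0.0 + 1e-9, 0.05)
    lon0, lat0 = known_site
    best = (None, np.inf)
    for a in angle_grid:
        pos = positions_from_twilights(tw, a)
        pos = pos.loc[pos["lat"].notna() & ~pos["lat_unresolved"]]
        if len(pos) == 0:
            continue
        d = great_circle_km(pos["lon"].to_numpy(), pos["lat"].to_numpy(), lon0, lat0)
        med = float(np.median(d))
        if med < best[1]:
            best = (float(a), med)
    if best[0] is None:
        raise InsufficientDataError("no calibration angle yielded resolvable positions")
    if not (-6.0 <= best[0] <= -3.0):
        warnings.warn(
            f"calibrated sun angle {best[0]:.2f} deg outside the usual [-6, -3] band",
            stacklevel=2,
        )
    return CalibrationResult(sun_angle_deg=best[0], residual_km=best[1])


# ---------------------------------------------------------------------------
# filtering & smoothing


def equinox_dates(year: int) -> Tuple[pd.Timestamp, pd.Timestamp]:
    """Dates (UTC) of the two declination zero-crossings of a year."""
    days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D") + pd.Timedelta(hours=12)
    decl, _ = solar.declination_eot(days)
    sign = np.sign(decl)
    idx = np.nonzero(sign[1:] != sign[:-1])[0]
    dates = [days[i].normalize() for i in idx[:2]]
    return tuple(dates)  # (March, September)


def filter_positions(
    track: Track,
    equinox_halfwidth_days: int = 20,
    speed_limit_kmh: float = 35.0,
    lon_jump_deg: float = 15.0,
) -> Track:
    """Apply the standard geolocation cleaning rules.

    Latitudes within ``equinox_halfwidth_days`` of either equinox are masked
    (longitudes kept — they are unaffected by the equinox problem);
    interference-flagged rows are dropped; a speed filter removes positions
    implying sustained travel above ``speed_limit_kmh`` to both neighbours;
    rows whose longitude departs from a 7-point rolling median by more than
    ``lon_jump_deg`` (mispaired or badly shaded twilights, which also evade
    the speed filter when the latitude is masked) are dropped.
    """
    out = track.copy()
    pos = out.positions.loc[~out.positions["interference"].astype(bool)].reset_index(drop=True)

    dates = pd.DatetimeIndex(pos["date"])
    masked = np.zeros(len(pos), dtype=bool)
    for year in np.unique(dates.year):
        for eq in equinox_dates(int(year)):
            masked |= np.abs((dates - eq).days) <= equinox_halfwidth_days
    pos.loc[masked, "lat"] = np.nan
    pos.loc[masked, "equinox_masked"] = True

    # longitude outlier screen (window median on unwrapped longitudes)
    if len(pos) >= 7:
        lon = pos["lon"].to_numpy(dtype=float)
        lon_un = np.degrees(np.unwrap(np.radians(lon)))
        med = pd.Series(lon_un).rolling(7, center=True, min_periods=3).median().to_numpy()
        bad = np.abs(lon_un - med) > lon_jump_deg
        if bad.any():
            log.warning("longitude filter removed %d position(s)", int(bad.sum()))
            pos = pos.loc[~bad].reset_index(drop=True)

    # iterative speed filter on rows with resolved latitude
    for _ in range(5):
        ok = pos["lat"].notna().to_numpy()
        idx = np.nonzero(ok)[0]
        if len(idx) < 3:
            break
        lon = pos["lon"].to_numpy()[idx]
        lat = pos["lat"].to_numpy()[idx]
        t = pd.DatetimeIndex(pos["timestamp"]).asi8[idx] / 3.6e12  # hours
        d_prev = great_circle_km(lon[1:], lat[1:], lon[:-1], lat[:-1])
        dt = np.maximum(np.diff(t), 1e-6)
        v = d_prev / dt
        spd_prev = np.concatenate([[0.0], v])
        spd_next = np.concatenate([v, [0.0]])
        bad = (spd_prev > speed_limit_kmh) & (spd_next > speed_limit_kmh)
        if not bad.any():
            break
        drop = idx[bad]
        log.warning("speed filter removed %d position(s)", len(drop))
        pos = pos.drop(index=pos.index[drop]).reset_index(drop=True)
    out.positions = pos
    return out


def _smooth_121(values: np.ndarray, seg_id: np.ndarray, passes: int = 2) -> np.ndarray:
    """1-2-1 weighted smoothing within segments, endpoints unchanged."""
    v = values.astype(float).copy()
    for _ in range(passes):
        nv = v.copy()
        for s in np.unique(seg_id):
            sel = np.nonzero(seg_id == s)[0]
            if len(sel) < 3:
                continue
            w = v[sel]
            nv[sel[1:-1]] = 0.25 * w[:-2] + 0.5 * w[1:-1] + 0.25 * w[2:]
        v = nv
    return v


def smooth_track(track: Track, max_gap_days: float = 3.0, passes: int = 2) -> Track:
    """Double smoothing of the filtered track (two 1-2-1 passes on lon and lat
    separately); gaps longer than ``max_gap_days`` are not bridged and masked
    latitudes are left missing."""
    out = track.copy()
    pos = out.positions
    if pos["lat"].notna().sum() < 3 and len(pos) < 3:
        warnings.warn("fewer than 3 positions: smoothing skipped", stacklevel=2)
        return out
    t_days = pd.DatetimeIndex(pos["timestamp"]).asi8 / 86.4e12

    def segments(valid: np.ndarray) -> np.ndarray:
        seg = np.full(len(valid), -1)
        cur = 0
        last_t = None
        for i in np.nonzero(valid)[0]:
            if last_t is not None and t_days[i] - last_t > max_gap_days:
                cur += 1
            seg[i] = cur
            last_t = t_days[i]
        return seg

    lon = pos["lon"].to_numpy(dtype=float)
    ok_lon = np.isfinite(lon)
    # unwrap longitudes so smoothing across the antimeridian is well behaved
    lon_un = lon.copy()
    lon_un[ok_lon] = np.degrees(np.unwrap(np.radians(lon[ok_lon])))
    sm = _smooth_121(np.where(ok_lon, lon_un, 0.0), segments(ok_lon), passes)
    lon_sm = np.where(ok_lon, (sm + 180.0) % 360.0 - 180.0, lon)

    lat = pos["lat"].to_numpy(dtype=float)
    ok_lat = np.isfinite(lat)
    seg_lat = segments(ok_lat)
    lat_sm = lat.copy()
    sm = _smooth_121(np.where(ok_lat, lat, 0.0), seg_lat, passes)
    lat_sm[ok_lat] = sm[ok_lat]

    pos = pos.copy()
    pos["lon"] = lon_sm
    pos["lat"] = lat_sm
    out.positions = pos
    return out
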