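"""Seeded forward simulator of the study's data-generating process.

Emulates a shearwater tracking campaign: birds from a known colony depart on
postbreeding migration (males a few days before females), transit along the
great circle to a sex-structured choice of wintering area, wander around the
wintering centroid (females over a wider core area), return, and reattend the
colony (males arriving earlier).  Their geolocators record clipped light
(max-over-interval, optionally shaded near twilight) and 10-min immersion
counts with a sex offset in nocturnal flight propensity.  Feather isotopes
take area baselines plus a male-positive offset in both d13C and d15N;
biometrics come from a shared-size-factor model with configurable dimorphism.

Every draw routes through one seeded generator, and everything injected is
recorded in a truth ledger so recovery tests can compare estimate to truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import solar

# Table-style defaults: study colonies (lon, lat)
COLONIES: Dict[str, Tuple[float, float]] = {
    "Pantaleu": (2.35, 39.57),
    "Vila": (-25.17, 36.94),
    "Montana Clara": (-13.53, 29.29),
    "Veneguera": (-15.78, 27.84),
    "Curral Velho": (-22.78, 15.96),
}

# schematic wintering-area centroids (inside the bundled catalog polygons)
AREA_CENTROIDS: Dict[str, Tuple[float, float]] = {
    "North Atlantic": (-35.0, 45.0),
    "Canary Current": (-18.0, 24.0),
    "Guinea Current": (-8.0, 4.0),
    "Benguela Current": (10.0, -25.0),
    "Agulhas Current": (30.0, -38.0),
    "South Atlantic": (-20.0, -42.0),
    "Brazil Current": (-48.0, -32.0),
}


@dataclass
class SimulationConfig:
    """All knobs of the simulator, with defaults set to the study conditions."""

    seed: int = 0
    n_per_sex: int = 10
    species: str = "Cory's shearwater"
    colony_name: str = "Veneguera"
    cycle_year: int = 2010

    # wintering-area choice probabilities per sex (order defines the draw)
    area_probs_male: Dict[str, float] = field(default_factory=lambda: {
        "Benguela Current": 0.55, "Canary Current": 0.20, "Agulhas Current": 0.07,
        "South Atlantic": 0.05, "North Atlantic": 0.08, "Brazil Current": 0.05,
    })
    area_probs_female: Dict[str, float] = field(default_factory=lambda: {
        "Benguela Current": 0.50, "Canary Current": 0.20, "Agulhas Current": 0.12,
        "South Atlantic": 0.05, "North Atlantic": 0.0, "Brazil Current": 0.13,
    })

    # phenology (day of cycle, cycle starts 1 July); males shifted earlier
    departure_mean_day: float = 130.0     # ~ 7 November for females
    departure_sd_days: float = 4.0
    male_departure_offset_days: float = -4.0
    arrival_colony_mean_day: float = 245.0  # ~ 3 March for females
    arrival_sd_days: float = 4.0
    male_arrival_offset_days: float = -3.0

    # movement
    transit_speed_km_day: float = 600.0
    wander_sd_km_male: float = 120.0
    wander_sd_km_female: float = 180.0
    colony_wander_sd_km: float = 40.0

    # logger model
    recording_interval_min: int = 10
    light_max: int = 64
    light_threshold: float = 20.0
    twilight_angle_deg: float = -4.5
    light_ramp_width_deg: float = 8.0
    shading_prob: float = 0.0            # per twilight-band interval
    twilight_jitter_min: float = 0.0     # gaussian jitter of the light clock

    # activity model (per-bin flight probabilities and persistence)
    p_fly_dark_male: float = 0.32
    p_fly_dark_female: float = 0.42
    p_fly_light: float = 0.50
    activity_persistence: float = 0.8
    p_wet_sitting: float = 0.98
    p_wet_flying: float = 0.02

    # isotope model: per-area (d13C, d15N) baselines, male-positive offsets
    isotope_baselines: Dict[str, Tuple[float, float]] = field(default_factory=lambda: {
        "North Atlantic": (-18.0, 11.5), "Canary Current": (-16.5, 12.5),
        "Guinea Current": (-16.0, 12.0), "Benguela Current": (-15.8, 13.5),
        "Agulhas Current": (-16.2, 13.0), "South Atlantic": (-17.5, 11.0),
        "Brazil Current": (-16.8, 12.2),
    })
    d13c_sex_offset: float = 0.2   # male minus female, permil
    d15n_sex_offset: float = 0.5
    isotope_individual_sd: Tuple[float, float] = (0.5, 0.6)
    measurement_sd: Tuple[float, float] = (0.2, 0.3)  # instrument error C, N

    # biometric model: female means (mm) and per-variable SSI targets (%)
    biometric_female_means: Dict[str, float] = field(default_factory=lambda: {
        "tarsus_mm": 54.0, "culmen_mm": 54.0, "head_bill_mm": 110.0,
        "bill_depth_base_mm": 17.0, "bill_depth_nostril_mm": 15.0,
    })
    biometric_ssi_percent: Dict[str, float] = field(default_factory=lambda: {
        "tarsus_mm": 3.5, "culmen_mm": 7.0, "head_bill_mm": 4.0,
        "bill_depth_base_mm": 9.0, "bill_depth_nostril_mm": 13.0,
    })
    biometric_shared_cv: float = 0.025   # shared size-factor coefficient of variation
    biometric_indep_cv: float = 0.008

    def validate(self) -> None:
        for name, probs in (("male", self.area_probs_male),
                            ("female", self.area_probs_female)):
            vals = np.array(list(probs.values()), dtype=float)
            if (vals < 0).any() or not np.isclose(vals.sum(), 1.0):
                raise ValueError(f"{name} area probabilities must be >= 0 and sum to 1")
            unknown = set(probs) - set(AREA_CENTROIDS)
            if unknown:
                raise ValueError(f"unknown wintering areas: {sorted(unknown)}")
        if self.n_per_sex < 1:
            raise ValueError("n_per_sex must be >= 1")

    @property
    def colony(self) -> Tuple[float, float]:
        return COLONIES[self.colony_name]


# ---------------------------------------------------------------------------
# movement


def _km_offsets_to_lonlat(lon0, lat0, dx_km, dy_km):
    dlat = dy_km / 111.195
    dlon = dx_km / (111.195 * np.cos(np.radians(lat0)))
    return lon0 + dlon, lat0 + dlat


def _great_circle_path(p0, p1, fracs):
    """Points along the great circle from p0 to p1 at fractions ``fracs``."""
    lon0, lat0 = np.radians(p0)
    lon1, lat1 = np.radians(p1)
    v0 = np.array([np.cos(lat0) * np.cos(lon0), np.cos(lat0) * np.sin(lon0), np.sin(lat0)])
    v1 = np.array([np.cos(lat1) * np.cos(lon1), np.cos(lat1) * np.sin(lon1), np.sin(lat1)])
    omega = np.arccos(np.clip(v0 @ v1, -1.0, 1.0))
    if omega < 1e-9:
        pts = np.outer(np.ones_like(fracs), v0)
    else:
        pts = (np.outer(np.sin((1 - fracs) * omega), v0) + np.outer(np.sin(fracs * omega), v1)) / np.sin(omega)
    lat = np.degrees(np.arcsin(np.clip(pts[:, 2], -1, 1)))
    lon = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
    return lon, lat


def simulate_track(
    colony: Tuple[float, float],
    wintering: Tuple[float, float],
    departure_day: int,
    arrival_colony_day: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    wander_sd_km: float,
    migratory: bool = True,
    n_days: int = 365,
) -> pd.DataFrame:
    """Daily true positions (at local noon of the cycle day) for one bird-cycle.

    Colony-centred wander before departure and after return; great-circle
    transit at the configured speed; wintering wander around the area
    centroid with the sex-specific spread.
    """
    from .space_use import great_circle_km

    start = pd.Timestamp(f"{config.cycle_year}-07-01")
    dates = start + pd.to_timedelta(np.arange(n_days), unit="D")
    lon = np.empty(n_days)
    lat = np.empty(n_days)

    if not migratory:
        dx = rng.normal(0, wander_sd_km, n_days)
        dy = rng.normal(0, wander_sd_km, n_days)
        lon, lat = _km_offsets_to_lonlat(colony[0], colony[1], dx, dy)
        truth = {"departure_colony": None, "arrival_wintering": None,
                 "departure_wintering": None, "arrival_colony": None}
    else:
        dist = great_circle_km(colony[0], colony[1], wintering[0], wintering[1])
        transit_days = max(int(np.ceil(dist / config.transit_speed_km_day)), 1)
        arr_w = departure_day + transit_days
        dep_w = arrival_colony_day - transit_days
        if dep_w <= arr_w + 1:
            raise ValueError("schedule leaves no residence window; check config")
        # colony phase
        nc = departure_day
        dx = rng.normal(0, config.colony_wander_sd_km, nc)
        dy = rng.normal(0, config.colony_wander_sd_km, nc)
        lon[:nc], lat[:nc] = _km_offsets_to_lonlat(colony[0], colony[1], dx, dy)
        # outbound transit (strictly between colony and centroid: the first
        # day *at* the centroid is the arrival day, not the last transit day)
        fr = (np.arange(departure_day, arr_w) - departure_day + 1) / (transit_days + 1)
        lon[departure_day:arr_w], lat[departure_day:arr_w] = _great_circle_path(colony, wintering, fr)
        # wintering residence
        nw = dep_w - arr_w
        dx = rng.normal(0, wander_sd_km, nw)
        dy = rng.normal(0, wander_sd_km, nw)
        lon[arr_w:dep_w], lat[arr_w:dep_w] = _km_offsets_to_lonlat(wintering[0], wintering[1], dx, dy)
        # return transit
        fr = (np.arange(dep_w, arrival_colony_day) - dep_w + 1) / (transit_days + 1)
        lon[dep_w:arrival_colony_day], lat[dep_w:arrival_colony_day] = _great_circle_path(wintering, colony, fr)
        # back at the colony
        nb = n_days - arrival_colony_day
        dx = rng.normal(0, config.colony_wander_sd_km, nb)
        dy = rng.normal(0, config.colony_wander_sd_km, nb)
        lon[arrival_colony_day:], lat[arrival_colony_day:] = _km_offsets_to_lonlat(colony[0], colony[1], dx, dy)
        truth = {
            "departure_colony": dates[departure_day],
            "arrival_wintering": dates[arr_w],
            "departure_wintering": dates[dep_w],
            "arrival_colony": dates[arrival_colony_day],
        }

    df = pd.DataFrame({"date": dates, "lon": lon, "lat": lat})
    df.attrs["truth"] = truth
    return df


def add_position_noise(
    positions: pd.DataFrame, mean_error_km: float = 186.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Isotropic Gaussian position noise with the given mean radial error.

    For a circular bivariate normal, mean radial error = sigma * sqrt(pi/2),
    so the per-axis sigma is mean_error_km / 1.2533.
    """
    rng = rng if rng is not None else np.random.default_rng()
    sigma = mean_error_km / np.sqrt(np.pi / 2.0)
    out = positions.copy()
    dx = rng.normal(0, sigma, len(out))
    dy = rng.normal(0, sigma, len(out))
    lon, lat = _km_offsets_to_lonlat(out["lon"].to_numpy(), out["lat"].to_numpy(), dx, dy)
    out["lon"], out["lat"] = lon, lat
    return out


# ---------------------------------------------------------------------------
# loggers


def simulate_light(
    positions: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Light series: per-minute light from sun elevation, max per interval.

    Light ramps linearly with sun elevation over ``light_ramp_width_deg``
    centred such that the level crosses ``light_threshold`` exactly when the
    sun sits at ``twilight_angle_deg`` — so the threshold method's "true" sun
    angle is a known config quantity.  Optional shading zeroes the sensor for
    whole recording intervals near twilight with probability ``shading_prob``.
    """
    dates = pd.DatetimeIndex(positions["date"])
    n_days = len(dates)
    step = config.recording_interval_min
    per_day = 24 * 60 // step
    # minute grid, one position per day
    t0 = dates[0]
    minutes = np.arange(n_days * 24 * 60)
    ts = t0 + pd.to_timedelta(minutes, unit="m")
    if config.twilight_jitter_min:
        ts = ts + pd.to_timedelta(
            np.repeat(rng.normal(0, config.twilight_jitter_min, n_days), 24 * 60), unit="m"
        )
    lon = np.repeat(positions["lon"].to_numpy(), 24 * 60)
    lat = np.repeat(positions["lat"].to_numpy(), 24 * 60)
    elev = solar.sun_elevation(ts.values, lon, lat)
    lo = config.twilight_angle_deg - config.light_ramp_width_deg * (
        config.light_threshold / config.light_max
    )
    light = np.clip(
        config.light_max * (elev - lo) / config.light_ramp_width_deg,
        0.0, config.light_max,
    )
    # max over each recording interval
    light = light.reshape(-1, step).max(axis=1)
    bin_ts = t0 + pd.to_timedelta(np.arange(n_days * per_day) * step, unit="m")
    if config.shading_prob > 0:
        # one short shading span (1-3 bins, sensor reads 0) per affected twilight
        binned_elev = elev.reshape(-1, step).mean(axis=1)
        band = (binned_elev > lo - 2.0) & (binned_elev < lo + config.light_ramp_width_deg + 2.0)
        edges = np.nonzero(np.diff(band.astype(int)))[0]
        starts = ([0] if band[0] else []) + [e + 1 for e in edges if band[e + 1]]
        ends = [e for e in edges if band[e]] + ([len(band) - 1] if band[-1] else [])
        for s, e in zip(starts, ends):
            if rng.random() < config.shading_prob:
                span = int(rng.integers(1, 3))
                k = int(rng.integers(s, e + 1))
                light[k:k + span] = 0.0
    out = pd.DataFrame({"timestamp": bin_ts, "light": light})
    return out


def simulate_immersion(
    positions: pd.DataFrame,
    sex: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    arrival_colony: Optional[pd.Timestamp] = None,
) -> pd.DataFrame:
    """10-min immersion bins from a persistent two-state fly/sit schedule.

    Flight propensity depends on day phase (dark/light at the bird's true
    position, using the configured twilight angle) and on sex at night.
    Nights after colony arrival are fully dry (bird ashore).  Returns
    ``timestamp, wet`` plus a boolean ``flying`` truth column.
    """
    dates = pd.DatetimeIndex(positions["date"])
    n_days = len(dates)
    per_day = 24 * 6
    n = n_days * per_day
    ts = dates[0] + pd.to_timedelta(np.arange(n) * 10, unit="m")
    lon = np.repeat(positions["lon"].to_numpy(), per_day)
    lat = np.repeat(positions["lat"].to_numpy(), per_day)
    elev = solar.sun_elevation((ts + pd.Timedelta(minutes=5)).values, lon, lat)
    dark = elev < config.twilight_angle_deg

    p_dark = config.p_fly_dark_male if sex == "male" else config.p_fly_dark_female
    p_target = np.where(dark, p_dark, config.p_fly_light)
    refresh = rng.random(n) > config.activity_persistence
    refresh[0] = True
    draw = rng.random(n) < p_target
    last = np.maximum.accumulate(np.where(refresh, np.arange(n), 0))
    flying = draw[last]

    p_wet = np.where(flying, config.p_wet_flying, config.p_wet_sitting)
    wet = rng.binomial(200, p_wet)

    if arrival_colony is not None:
        ashore_night = dark & (ts >= pd.Timestamp(arrival_colony).normalize() + pd.Timedelta(hours=12))
        wet = np.where(ashore_night, 0, wet)
        flying = np.where(ashore_night, False, flying)
    return pd.DataFrame({"timestamp": ts, "wet": wet, "flying": flying})


# ---------------------------------------------------------------------------
# population


def _male_mean(female_mean: float, ssi_percent: float) -> float:
    # invert SSI = (m - f) / (0.5 (m + f)) * 100
    return female_mean * (200.0 + ssi_percent) / (200.0 - ssi_percent)


def simulate_population(config: SimulationConfig):
    """Draw the bird roster: metadata, biometrics, isotopes and truth ledger.

    Returns ``(metadata, biometrics, isotopes, ledger)`` where the first three
    are tidy DataFrames and the ledger maps bird_id to its injected truth
    (wintering area, schedule days, wander spread).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta_rows, bio_rows, iso_rows = [], [], []
    ledger: Dict[str, dict] = {"config": config}

    for sex in ("male", "female"):
        probs = config.area_probs_male if sex == "male" else config.area_probs_female
        names = list(probs)
        p = np.array([probs[a] for a in names])
        dep_off = config.male_departure_offset_days if sex == "male" else 0.0
        arr_off = config.male_arrival_offset_days if sex == "male" else 0.0
        wander = config.wander_sd_km_male if sex == "male" else config.wander_sd_km_female
        for i in range(config.n_per_sex):
            bird_id = f"{sex[0].upper()}{i + 1:03d}"
            area = names[rng.choice(len(names), p=p)]
            dep = int(round(rng.normal(config.departure_mean_day + dep_off,
                                       config.departure_sd_days)))
            arr = int(round(rng.normal(config.arrival_colony_mean_day + arr_off,
                                       config.arrival_sd_days)))
            meta_rows.append({"bird_id": bird_id, "sex": sex, "species": config.species,
                              "colony": config.colony_name,
                              "colony_lon": config.colony[0], "colony_lat": config.colony[1]})
            ledger[bird_id] = {
                "sex": sex, "area": area, "wander_sd_km": wander,
                "departure_day": dep, "arrival_colony_day": arr,
            }

            # biometrics: shared size factor + independent noise, sex mean shift
            z = rng.normal()
            row = {"bird_id": bird_id, "sex": sex, "species": config.species}
            for var, fmean in config.biometric_female_means.items():
                s = config.biometric_ssi_percent[var]
                mean = _male_mean(fmean, s) if sex == "male" else fmean
                row[var] = mean * (1.0 + config.biometric_shared_cv * z
                                   + config.biometric_indep_cv * rng.normal())
            bio_rows.append(row)

            # isotopes: area baseline + sex offset + individual + instrument noise
            base_c, base_n = config.isotope_baselines[area]
            off_c = config.d13c_sex_offset if sex == "male" else 0.0
            off_n = config.d15n_sex_offset if sex == "male" else 0.0
            d13c = (base_c + off_c + rng.normal(0, config.isotope_individual_sd[0])
                    + rng.normal(0, config.measurement_sd[0]))
            d15n = (base_n + off_n + rng.normal(0, config.isotope_individual_sd[1])
                    + rng.normal(0, config.measurement_sd[1]))
            iso_rows.append({"bird_id": bird_id, "sex": sex, "species": config.species,
                             "area": area, "year": config.cycle_year,
                             "d13C": d13c, "d15N": d15n})

    return (pd.DataFrame(meta_rows), pd.DataFrame(bio_rows),
            pd.DataFrame(iso_rows), ledger)


def simulate_bird_tracks(config: SimulationConfig, ledger: Dict[str, dict],
                         rng: Optional[np.random.Generator] = None) -> Dict[str, pd.DataFrame]:
    """True daily positions for every bird in the ledger (adds truth dates)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    tracks = {}
    for bird_id, info in ledger.items():
        if bird_id == "config":
            continue
        tr = simulate_track(
            config.colony, AREA_CENTROIDS[info["area"]],
            info["departure_day"], info["arrival_colony_day"],
            config, rng, info["wander_sd_km"],
        )
        info.update(tr.attrs["truth"])
        tracks[bird_id] = tr
    return tracks
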