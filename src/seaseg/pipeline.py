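"""One-call orchestration of the full sexual-segregation analysis.

``run_pipeline`` executes the stages in dependency order on a simulated
campaign (or, stage by stage, on logger files read with :mod:`seaseg.io`):

    simulate -> (twilights -> calibrate -> positions) or truth+noise
    -> filter/smooth -> phenology schedules -> kernels / areas / overlap
    -> activity & NFI -> isotope niches -> segregation statistics

Per-bird failures are logged and collected, not raised, so one bad logger
does not abort a batch.  Every output is a CSV/GeoJSON under the configured
output directory, plus a JSON manifest of parameters and seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import activity, comparative_stats, geolocation, io, isotope_niche, phenology, space_use
from .synthetic_data import (
    SimulationConfig,
    add_position_noise,
    simulate_bird_tracks,
    simulate_immersion,
    simulate_light,
    simulate_population,
)

log = logging.getLogger(__name__)


def geolocate_bird(
    light: pd.DataFrame,
    colony,
    calibration_window,
    threshold: float = 20.0,
    equinox_halfwidth_days: int = 20,
    speed_limit_kmh: float = 35.0,
    bird_id: str = "",
    sex: str = "",
    species: str = "",
) -> tuple:
    """Full inverse chain for one bird: light -> smoothed track.

    Returns ``(track, calibration)``.
    """
    tw = geolocation.detect_twilights(light, threshold=threshold)
    cal = geolocation.calibrate_sun_angle(tw, colony, calibration_window)
    tw_clean = geolocation.drop_interference(tw)
    pos = geolocation.positions_from_twilights(tw_clean, cal.sun_angle_deg)
    track = geolocation.Track(bird_id, sex, species, tuple(colony), pos)
    track = geolocation.filter_positions(track, equinox_halfwidth_days, speed_limit_kmh)
    track = geolocation.smooth_track(track)
    return track, cal


def run_pipeline(config: Optional[dict] = None, output_dir=None) -> dict:
    """Run the whole analysis on a simulated campaign; returns a result bundle.

    ``config`` follows :data:`seaseg.io.DEFAULT_CONFIG` (validated; unknown
    keys rejected).  The bundle maps stage names to DataFrames/objects and is
    also written out as CSV files plus ``manifest.json``.
    """
    cfg = io.validate_config(config or {})
    outdir = Path(output_dir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    sim_cfg = SimulationConfig(**{"seed": cfg["seed"], **cfg["simulate"]})
    meta, biometrics, isotopes, ledger = simulate_population(sim_cfg)
    tracks_true = simulate_bird_tracks(sim_cfg, ledger)
    rng = np.random.default_rng(sim_cfg.seed + 2)

    failures = {}
    tracks = {}
    calibrations = {}
    immersions = {}
    for _, row in meta.iterrows():
        bird_id = row["bird_id"]
        truth = tracks_true[bird_id]
        try:
            if cfg["position_source"] == "geolocation":
                light = simulate_light(truth, sim_cfg, rng)
                dep_day = ledger[bird_id]["departure_day"]
                cal_end = truth["date"].iloc[0] + pd.Timedelta(days=min(7, dep_day))
                track, cal = geolocate_bird(
                    light, sim_cfg.colony, (truth["date"].iloc[0], cal_end),
                    threshold=cfg["light_threshold"],
                    equinox_halfwidth_days=cfg["equinox_halfwidth_days"],
                    speed_limit_kmh=cfg["speed_limit_kmh"],
                    bird_id=bird_id, sex=row["sex"], species=row["species"],
                )
                calibrations[bird_id] = cal
            else:
                pos = truth.copy()
                if cfg["position_source"] == "truth+noise":
                    pos = add_position_noise(pos, cfg["position_noise_km"], rng)
                pos = pos.rename(columns={"date": "timestamp"})
                pos["date"] = pd.DatetimeIndex(pos["timestamp"]).normalize()
                pos["half"] = "AM"
                pos["interference"] = False
                pos["lat_unresolved"] = False
                pos["equinox_masked"] = False
                track = geolocation.Track(
                    bird_id, row["sex"], row["species"], sim_cfg.colony,
                    pos[["date", "half", "timestamp", "lon", "lat",
                         "interference", "lat_unresolved", "equinox_masked"]],
                )
                track = geolocation.smooth_track(track)
            tracks[bird_id] = track
            immersions[bird_id] = simulate_immersion(
                truth, row["sex"], sim_cfg, rng,
                arrival_colony=ledger[bird_id].get("arrival_colony"),
            )
        except Exception as exc:  # collected, not raised: batch continues
            log.warning("bird %s failed geolocation: %s", bird_id, exc)
            failures[bird_id] = str(exc)

    # ---- phenology -------------------------------------------------------
    schedules = []
    for bird_id, track in tracks.items():
        try:
            sched = phenology.build_schedule(
                track, immersions.get(bird_id), cycle_year=sim_cfg.cycle_year,
                window_days=cfg["phenology_window_days"],
                radius_km=cfg["phenology_radius_km"],
                speed_km_day=cfg["phenology_speed_km_day"],
                resident_radius_km=cfg["resident_radius_km"],
                sun_angle_deg=sim_cfg.twilight_angle_deg,
            )
            schedules.append(sched)
        except Exception as exc:
            log.warning("bird %s failed phenology: %s", bird_id, exc)
            failures[bird_id] = str(exc)
    schedule_df = phenology.schedule_table(schedules)

    # ---- space use -------------------------------------------------------
    catalog = space_use.load_area_catalog()
    assign_rows = []
    kernels = {}
    wintering_positions = {}
    for bird_id, track in tracks.items():
        sched = next((s for s in schedules if s.bird_id == bird_id), None)
        pos = track.positions
        if sched is not None and sched.arrival_wintering is not None:
            sel = (pd.DatetimeIndex(pos["date"]) >= sched.arrival_wintering)
            if sched.departure_wintering is not None:
                sel &= pd.DatetimeIndex(pos["date"]) <= sched.departure_wintering
            pos = pos.loc[sel]
        lat_ok = pos["lat"].notna()
        try:
            k = space_use.kernel_ud(
                pos.loc[lat_ok, "lon"], pos.loc[lat_ok, "lat"],
                cfg["kernel_bandwidth_km"], cfg["kernel_cell_km"],
            )
        except space_use.InsufficientPositionsError as exc:
            log.warning("bird %s: %s", bird_id, exc)
            failures[bird_id] = str(exc)
            continue
        kernels[bird_id] = k
        area50, area95, centroid, _ = space_use.summarize_ud(k)
        area = space_use.assign_area(centroid, catalog)
        dist = space_use.great_circle_km(
            centroid[0], centroid[1], sim_cfg.colony[0], sim_cfg.colony[1]
        )
        wintering_positions[bird_id] = pos.loc[lat_ok, ["lon", "lat"]]
        assign_rows.append({
            "bird_id": bird_id, "sex": track.sex, "area": area,
            "centroid_lon": centroid[0], "centroid_lat": centroid[1],
            "area50_km2": area50, "area95_km2": area95,
            "colony_distance_km": dist,
        })
    assignments = pd.DataFrame(assign_rows)

    # sex-level kernels and male/female overlap on the pooled wintering areas
    overlap_rows = []
    if len(assignments):
        for area_name, grp in assignments.groupby("area"):
            by_sex = {}
            for sex in ("male", "female"):
                ids = grp.loc[grp["sex"] == sex, "bird_id"]
                pts = pd.concat([wintering_positions[b] for b in ids], ignore_index=True) \
                    if len(ids) else pd.DataFrame(columns=["lon", "lat"])
                if len(pts) >= 5:
                    by_sex[sex] = space_use.kernel_ud(
                        pts["lon"], pts["lat"],
                        cfg["kernel_bandwidth_km"], cfg["kernel_cell_km"],
                    )
            if len(by_sex) == 2:
                for level in (50, 95):
                    ov = space_use.hr_overlap(by_sex["male"], by_sex["female"], level)
                    overlap_rows.append({
                        "area": area_name, "level": level,
                        "overlap_male_female": ov.overlap_ab,
                        "overlap_female_male": ov.overlap_ba,
                    })
    overlaps = pd.DataFrame(overlap_rows)

    # ---- chi-square sex x area -----------------------------------------
    chi = None
    if len(assignments):
        table = comparative_stats.sex_area_table(assignments)
        if table.shape[0] == 2 and table.shape[1] >= 2:
            chi = comparative_stats.pearson_chi_square(table.to_numpy())

    # ---- activity / NFI --------------------------------------------------
    nfi_rows = []
    for bird_id, imm in immersions.items():
        sched = next((s for s in schedules if s.bird_id == bird_id), None)
        if sched is None or sched.arrival_wintering is None or sched.departure_wintering is None:
            continue
        truth = tracks_true[bird_id]
        per_day = 24 * 6
        lon = np.repeat(truth["lon"].to_numpy(), per_day)[: len(imm)]
        lat = np.repeat(truth["lat"].to_numpy(), per_day)[: len(imm)]
        labelled = activity.classify_light_dark(imm, lon, lat, sim_cfg.twilight_angle_deg)
        daily = activity.daily_activity_table(labelled)
        try:
            mean_nfi, window = activity.mean_nfi_lunar_window(
                daily, (sched.arrival_wintering, sched.departure_wintering),
                cfg["nfi_window_days"],
            )
        except activity.InsufficientCoverageError as exc:
            log.warning("bird %s NFI: %s", bird_id, exc)
            continue
        sex = next(t.sex for b, t in tracks.items() if b == bird_id)
        nfi_rows.append({"bird_id": bird_id, "sex": sex, "mean_nfi": mean_nfi,
                         "window_start": window[0], "window_end": window[1]})
    nfi_df = pd.DataFrame(nfi_rows)

    # ---- isotope niches --------------------------------------------------
    niches = {}
    seab_result = None
    xy = {s: isotopes.loc[isotopes["sex"] == s, ["d13C", "d15N"]].to_numpy()
          for s in ("male", "female")}
    if all(len(v) >= isotope_niche.MIN_GROUP_SIZE for v in xy.values()):
        for s, v in xy.items():
            niches[s] = isotope_niche.fit_niche(v, label=s, n_draws=cfg["seab_draws"],
                                                seed=sim_cfg.seed + 10)
        seab_result = isotope_niche.seab(xy["male"], xy["female"],
                                         n_draws=cfg["seab_draws"],
                                         seed=sim_cfg.seed + 11)

    # ---- SSI / bill PCA --------------------------------------------------
    ssi_rows = []
    for var in SimulationConfig().biometric_female_means:
        m = biometrics.loc[biometrics["sex"] == "male", var].mean()
        f = biometrics.loc[biometrics["sex"] == "female", var].mean()
        ssi_rows.append({"variable": var, "ssi_percent": comparative_stats.ssi(m, f)})
    ssi_df = pd.DataFrame(ssi_rows)
    if len(biometrics) >= 5:
        pc1, var_frac = comparative_stats.bill_pca(biometrics)
    else:
        pc1, var_frac = None, np.array([np.nan])

    # ---- outputs ---------------------------------------------------------
    io.write_table(meta, outdir / "metadata.csv")
    io.write_table(biometrics, outdir / "biometrics.csv")
    io.write_table(isotopes, outdir / "isotopes.csv")
    io.write_table(schedule_df, outdir / "schedules.csv")
    io.write_table(assignments, outdir / "area_assignments.csv")
    io.write_table(overlaps, outdir / "overlaps.csv")
    io.write_table(nfi_df, outdir / "nfi.csv")
    io.write_table(ssi_df, outdir / "ssi.csv")
    manifest = {
        "config": cfg,
        "simulation": {k: v for k, v in asdict(sim_cfg).items()},
        "n_birds": int(len(meta)),
        "failures": failures,
        "chi_square": None if chi is None else
            {"statistic": chi.statistic, "df": chi.df, "p": chi.p},
        "pc1_variance_fraction": float(var_frac[0]),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {
        "metadata": meta, "biometrics": biometrics, "isotopes": isotopes,
        "ledger": ledger, "tracks": tracks, "tracks_true": tracks_true,
        "calibrations": calibrations, "schedules": schedule_df,
        "assignments": assignments, "overlaps": overlaps, "chi_square": chi,
        "nfi": nfi_df, "niches": niches, "seab": seab_result,
        "ssi": ssi_df, "pc1": pc1, "pc1_variance": var_frac,
        "failures": failures,
    }
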