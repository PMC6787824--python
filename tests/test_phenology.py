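"""Migration event detection and schedule assembly."""

import numpy as np
import pandas as pd
import pytest

from seaseg import phenology as ph
from seaseg.space_use import great_circle_km
from seaseg.synthetic_data import (
    SimulationConfig,
    add_position_noise,
    simulate_immersion,
    simulate_track,
)

from conftest import truth_positions_as_track


@pytest.fixture(scope="module")
def track(migratory_track):
    return truth_positions_as_track(
        migratory_track["positions"], migratory_track["config"].colony
    )


class TestDetectTransition:
    def test_noiseless_departure_exact(self, migratory_track, track):
        dep = ph.detect_transition(track, "departure")
        truth = migratory_track["truth"]["departure_colony"]
        assert abs((dep - truth).days) <= 1

    def test_noiseless_arrival_within_a_day(self, migratory_track, track):
        dep = ph.detect_transition(track, "departure")
        arr = ph.detect_transition(track, "arrival",
                                   start_date=dep + pd.Timedelta(days=2))
        truth = migratory_track["truth"]["arrival_wintering"]
        assert abs((arr - truth).days) <= 1

    def test_stationary_track_has_no_transition(self):
        dates = pd.date_range("2010-07-01", periods=120, freq="D")
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "date": dates,
            "lon": -15.78 + rng.normal(0, 0.3, len(dates)),
            "lat": 27.84 + rng.normal(0, 0.3, len(dates)),
        })
        tr = truth_positions_as_track(df, (-15.78, 27.84))
        with pytest.raises(ph.TransitionNotFound):
            ph.detect_transition(tr, "departure")

    def test_noisy_recovery_rate(self, migratory_track):
        """Departure within +-3 days of truth in >= 90% of noisy replicates."""
        truth = migratory_track["truth"]["departure_colony"]
        colony = migratory_track["config"].colony
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            noisy = add_position_noise(
                migratory_track["positions"], 186.0, np.random.default_rng(300 + rep)
            )
            tr = truth_positions_as_track(noisy, colony)
            try:
                dep = ph.detect_transition(tr, "departure")
                hits += abs((dep - truth).days) <= 3
            except ph.TransitionNotFound:
                pass
        assert hits / n_rep >= 0.9

    def test_longitude_rotation_invariance(self, migratory_track, track):
        """A track rotated across the antimeridian gives the same dates."""
        dep0 = ph.detect_transition(track, "departure")
        rotated = migratory_track["positions"].copy()
        rotated["lon"] = ((rotated["lon"] + 120.0 + 180.0) % 360.0) - 180.0
        tr2 = truth_positions_as_track(rotated, migratory_track["config"].colony)
        dep1 = ph.detect_transition(tr2, "departure")
        assert dep0 == dep1


class TestColonyArrivalFromDry:
    def test_generator_truth_recovered_exactly(self, migratory_track):
        cfg = migratory_track["config"]
        truth = migratory_track["truth"]
        imm = simulate_immersion(
            migratory_track["positions"], "male", cfg, np.random.default_rng(7),
            arrival_colony=truth["arrival_colony"],
        )
        got = ph.colony_arrival_from_dry(
            imm, cfg.colony[0], cfg.colony[1], cfg.twilight_angle_deg,
            start_date=truth["departure_wintering"],
        )
        assert got == truth["arrival_colony"]

    def test_bird_at_sea_every_night_not_found(self, migratory_track):
        cfg = migratory_track["config"]
        imm = simulate_immersion(
            migratory_track["positions"], "male", cfg, np.random.default_rng(8),
            arrival_colony=None,
        )
        with pytest.raises(ph.TransitionNotFound):
            ph.colony_arrival_from_dry(imm, cfg.colony[0], cfg.colony[1],
                                       cfg.twilight_angle_deg)

    def test_single_wet_bin_rejects_night(self, migratory_track):
        cfg = migratory_track["config"]
        truth = migratory_track["truth"]
        imm = simulate_immersion(
            migratory_track["positions"], "male", cfg, np.random.default_rng(9),
            arrival_colony=truth["arrival_colony"],
        )
        # poison one bin in the middle of the first colony night
        first_night = pd.Timestamp(truth["arrival_colony"]).normalize() + pd.Timedelta(hours=23)
        idx = int(np.abs((pd.DatetimeIndex(imm["timestamp"]) - first_night)
                         .total_seconds()).argmin())
        imm.loc[imm.index[idx], "wet"] = 1
        got = ph.colony_arrival_from_dry(
            imm, cfg.colony[0], cfg.colony[1], cfg.twilight_angle_deg,
            start_date=truth["departure_wintering"],
        )
        assert got == truth["arrival_colony"] + pd.Timedelta(days=1)


class TestClassifyMigratory:
    def test_centroid_at_colony_is_resident(self):
        assert not ph.classify_migratory((-15.78, 27.84), (-15.78, 27.84))

    def test_benguela_centroid_is_migratory(self):
        d = great_circle_km(-15.78, 27.84, 10.0, -25.0)
        assert d > 1000.0
        assert ph.classify_migratory((10.0, -25.0), (-15.78, 27.84))

    def test_boundary_is_resident_by_strict_inequality(self):
        colony = (-15.78, 27.84)
        pt = (-15.78, 27.84 + 9.0)
        d = great_circle_km(colony[0], colony[1], pt[0], pt[1])
        assert not ph.classify_migratory(pt, colony, resident_radius_km=d)


class TestBuildSchedule:
    def test_duration_arithmetic(self):
        s = ph.MigrationSchedule(
            "b", 2010,
            departure_colony=pd.Timestamp("2010-10-28"),
            arrival_wintering=pd.Timestamp("2010-11-09"),
            departure_wintering=pd.Timestamp("2011-01-30"),
            arrival_colony=pd.Timestamp("2011-02-27"),
        )
        assert s.transit_out_days == 12
        assert s.transit_return_days == 28
        assert s.total_nonbreeding_days == (s.arrival_colony - s.departure_colony).days

    def test_schedule_internally_consistent(self, migratory_track, track):
        s = ph.build_schedule(track, cycle_year=2010)
        assert s.migratory
        assert s.departure_colony <= s.arrival_wintering
        assert s.arrival_wintering <= s.departure_wintering
        assert s.departure_wintering <= s.arrival_colony
        assert s.total_nonbreeding_days == (
            s.transit_out_days + s.days_in_area + s.transit_return_days
        )

    def test_nonmigratory_bird_has_no_transit_fields(self):
        cfg = SimulationConfig(seed=21)
        rng = np.random.default_rng(21)
        tr = simulate_track(cfg.colony, cfg.colony, 0, 0, cfg, rng,
                            wander_sd_km=60.0, migratory=False)
        track = truth_positions_as_track(tr, cfg.colony)
        s = ph.build_schedule(track, cycle_year=2010)
        assert not s.migratory
        assert s.departure_colony is None
        assert s.transit_out_days is None

    def test_sex_departure_offset_recovered(self):
        """Cohorts with a -4 day male departure shift recover 4 +- 2 days."""
        cfg = SimulationConfig(seed=31)
        rng = np.random.default_rng(31)
        deps = {"male": [], "female": []}
        for sex in ("male", "female"):
            off = -4 if sex == "male" else 0
            for i in range(10):
                day = int(round(rng.normal(130 + off, 4)))
                tr = simulate_track(cfg.colony, (10.0, -25.0), day, 245, cfg, rng, 150.0)
                track = truth_positions_as_track(tr, cfg.colony)
                dep = ph.detect_transition(track, "departure")
                deps[sex].append((dep - pd.Timestamp("2010-07-01")).days)
        diff = np.mean(deps["male"]) - np.mean(deps["female"])
        assert diff == pytest.approx(-4.0, abs=2.0 + 2 * 4 / np.sqrt(10))
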