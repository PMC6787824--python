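"""Shared fixtures: small simulated deployments reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seaseg.synthetic_data import SimulationConfig, simulate_light, simulate_track

VENEGUERA = (-15.78, 27.84)


@pytest.fixture(scope="session")
def fixed_site_light():
    """40 days of clean simulated light at the Veneguera colony, true sun
    angle -4.5 deg (July-August: far from the equinoxes)."""
    cfg = SimulationConfig(seed=11, twilight_angle_deg=-4.5)
    dates = pd.date_range("2010-07-01", periods=40, freq="D")
    pos = pd.DataFrame({"date": dates, "lon": VENEGUERA[0], "lat": VENEGUERA[1]})
    light = simulate_light(pos, cfg, np.random.default_rng(11))
    return {"light": light, "dates": dates, "site": VENEGUERA, "true_angle": -4.5}


@pytest.fixture(scope="session")
def migratory_track():
    """One migratory bird-cycle Veneguera -> Benguela with known truth."""
    cfg = SimulationConfig(seed=5)
    rng = np.random.default_rng(5)
    tr = simulate_track(cfg.colony, (10.0, -25.0), 126, 242, cfg, rng, 150.0)
    return {"config": cfg, "positions": tr, "truth": tr.attrs["truth"]}


def truth_positions_as_track(df: pd.DataFrame, colony, bird_id="b1",
                             sex="male", species="test"):
    """Wrap a daily true-position frame in the Track container."""
    from seaseg.geolocation import Track

    pos = df.rename(columns={"date": "timestamp"}).copy()
    pos["date"] = pd.DatetimeIndex(pos["timestamp"]).normalize()
    pos["half"] = "AM"
    pos["interference"] = False
    pos["lat_unresolved"] = False
    pos["equinox_masked"] = False
    cols = ["date", "half", "timestamp", "lon", "lat",
            "interference", "lat_unresolved", "equinox_masked"]
    return Track(bird_id, sex, species, tuple(colony), pos[cols])
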