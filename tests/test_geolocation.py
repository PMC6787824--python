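"""Threshold geolocation: twilight detection, calibration, inversion, filters."""

import numpy as np
import pandas as pd
import pytest

from seaseg import geolocation as geo
from seaseg import solar
from seaseg.space_use import great_circle_km
from seaseg.synthetic_data import SimulationConfig, simulate_light

from conftest import truth_positions_as_track


def square_wave_light(n_days=3, sunrise_h=6, sunset_h=18, interval_min=10,
                      start="2010-07-01"):
    ts = pd.date_range(start, periods=n_days * 24 * 60 // interval_min,
                       freq=f"{interval_min}min")
    hours = ts.hour + ts.minute / 60.0
    light = np.where((hours >= sunrise_h) & (hours < sunset_h), 64.0, 0.0)
    return pd.DataFrame({"timestamp": ts, "light": light})


class TestDetectTwilights:
    def test_square_wave_clean_edges(self):
        light = square_wave_light()
        tw = geo.detect_twilights(light, threshold=20)
        sunrises = tw.loc[tw["kind"] == "sunrise", "timestamp"]
        sunsets = tw.loc[tw["kind"] == "sunset", "timestamp"]
        assert len(sunrises) == 3 and len(sunsets) == 3
        assert not tw["interference"].any()
        for t in sunrises:
            err = abs((t - t.normalize() - pd.Timedelta(hours=6)).total_seconds())
            assert err <= 5 * 60
        for t in sunsets:
            err = abs((t - t.normalize() - pd.Timedelta(hours=18)).total_seconds())
            assert err <= 5 * 60

    def test_night_spike_flagged_and_removable(self):
        light = square_wave_light()
        spike = (light["timestamp"].dt.day == 2) & (light["timestamp"].dt.hour == 2) \
            & (light["timestamp"].dt.minute == 0)
        light.loc[spike, "light"] = 40.0
        tw = geo.detect_twilights(light, threshold=20)
        assert tw["interference"].sum() == 2  # up- and down-crossing of the spike
        clean = geo.drop_interference(tw)
        assert len(clean) == 6
        assert list(clean["kind"]) == ["sunrise", "sunset"] * 3

    def test_never_crossing_gives_empty(self):
        ts = pd.date_range("2010-07-01", periods=288, freq="10min")
        light = pd.DataFrame({"timestamp": ts, "light": np.full(288, 5.0)})
        assert len(geo.detect_twilights(light)) == 0

    def test_simulated_light_matches_solar_prediction(self, fixed_site_light):
        tw = geo.detect_twilights(fixed_site_light["light"], threshold=20)
        lon, lat = fixed_site_light["site"]
        day = pd.Timestamp("2010-07-10")
        sr_pred, ss_pred, _ = solar.day_length_and_twilights(
            day, lon, lat, fixed_site_light["true_angle"])
        got_sr = tw.loc[(tw["kind"] == "sunrise")
                        & (pd.DatetimeIndex(tw["timestamp"]).normalize() == day),
                        "timestamp"].iloc[0]
        got_ss = tw.loc[(tw["kind"] == "sunset")
                        & (pd.DatetimeIndex(tw["timestamp"]).normalize() == day),
                        "timestamp"].iloc[0]
        assert abs((got_sr - sr_pred).total_seconds()) <= 600
        assert abs((got_ss - ss_pred).total_seconds()) <= 600

    def test_idempotent_on_reconstructed_square_wave(self):
        light = square_wave_light()
        tw1 = geo.detect_twilights(light, threshold=20)
        # rebuild a square wave from the detected events and re-detect
        ts = light["timestamp"]
        state = np.zeros(len(ts))
        for _, ev in tw1.iterrows():
            if ev["kind"] == "sunrise":
                state[ts >= ev["timestamp"]] = 64.0
            else:
                state[ts >= ev["timestamp"]] = 0.0
        tw2 = geo.detect_twilights(pd.DataFrame({"timestamp": ts, "light": state}))
        assert len(tw2) == len(tw1)
        dt = (pd.DatetimeIndex(tw2["timestamp"]) - pd.DatetimeIndex(tw1["timestamp"]))
        assert np.all(np.abs(dt.total_seconds()) <= 600)


class TestCalibration:
    def test_recovers_true_angle_noiseless(self, fixed_site_light):
        tw = geo.detect_twilights(fixed_site_light["light"], threshold=20)
        dates = fixed_site_light["dates"]
        cal = geo.calibrate_sun_angle(tw, fixed_site_light["site"],
                                      (dates[0], dates[7]))
        assert cal.sun_angle_deg == pytest.approx(
            fixed_site_light["true_angle"], abs=0.1)

    def test_jittered_twilights_recover_within_half_degree(self):
        cfg = SimulationConfig(seed=3, twilight_angle_deg=-3.0, twilight_jitter_min=2.0)
        dates = pd.date_range("2010-07-01", periods=10, freq="D")
        pos = pd.DataFrame({"date": dates, "lon": -15.78, "lat": 27.84})
        light = simulate_light(pos, cfg, np.random.default_rng(3))
        tw = geo.detect_twilights(light, threshold=20)
        with pytest.warns(UserWarning):
            cal = geo.calibrate_sun_angle(tw, (-15.78, 27.84), (dates[0], dates[9]))
        assert -3.5 <= cal.sun_angle_deg <= -2.5

    def test_three_days_insufficient(self, fixed_site_light):
        tw = geo.detect_twilights(fixed_site_light["light"], threshold=20)
        dates = fixed_site_light["dates"]
        with pytest.raises(geo.InsufficientDataError):
            geo.calibrate_sun_angle(tw, fixed_site_light["site"],
                                    (dates[0], dates[2]))


class TestPositionInversion:
    def _twilight_pair(self, date, midpoint_h, day_len_h):
        half = pd.Timedelta(hours=day_len_h / 2)
        mid = pd.Timestamp(date) + pd.Timedelta(hours=midpoint_h)
        return pd.DataFrame({
            "timestamp": [mid - half, mid + half],
            "kind": ["sunrise", "sunset"],
            "interference": [False, False],
        })

    def test_noon_midpoint_gives_zero_longitude(self):
        # mid-June: equation of time within ~0.1 min of zero
        tw = self._twilight_pair("2010-06-13", 12.0, 12.0)
        pos = geo.positions_from_twilights(tw, 0.0)
        assert abs(pos["lon"].iloc[0]) < 0.2

    def test_two_hour_late_midpoint_gives_minus_30(self):
        tw = self._twilight_pair("2010-06-13", 14.0, 12.0)
        pos = geo.positions_from_twilights(tw, 0.0)
        assert pos["lon"].iloc[0] == pytest.approx(-30.0, abs=0.2)

    def test_day_length_inversion_recovers_latitude_magnitude(self):
        # near-equinox date so declination ~ 0: 13.61 h at -6 deg -> |lat| = 60
        tw = self._twilight_pair("2010-03-20", 12.0, 13.609)
        pos = geo.positions_from_twilights(tw, -6.0)
        assert bool(pos["lat_unresolved"].iloc[0])
        assert abs(pos["lat"].iloc[0]) == pytest.approx(60.0, abs=0.5)

    def test_roundtrip_at_fixed_site(self, fixed_site_light):
        tw = geo.detect_twilights(fixed_site_light["light"], threshold=20)
        pos = geo.positions_from_twilights(tw, fixed_site_light["true_angle"])
        lon0, lat0 = fixed_site_light["site"]
        d = great_circle_km(pos["lon"], pos["lat"], lon0, lat0)
        assert np.nanmedian(d) < 0.5 * 111.2


class TestFilters:
    def _site_track(self, dates, lon, lat):
        df = pd.DataFrame({"date": dates, "lon": lon, "lat": lat})
        return truth_positions_as_track(df, (-15.78, 27.84))

    def test_equinox_mask_keeps_longitude(self):
        dates = pd.date_range("2010-09-01", periods=60, freq="D")
        tr = self._site_track(dates, np.full(60, -15.0), np.full(60, 27.0))
        out = geo.filter_positions(tr)
        pos = out.positions
        eq = pos["equinox_masked"]
        assert eq.any()
        assert pos.loc[eq, "lat"].isna().all()
        assert pos.loc[eq, "lon"].notna().all()
        # 30+ days from either equinox: untouched
        far = ~eq
        assert pos.loc[far, "lat"].notna().all()

    def test_speed_filter_removes_single_day_jump(self):
        dates = pd.date_range("2010-07-01", periods=30, freq="D")
        lon = np.full(30, -15.0)
        lat = np.full(30, 27.0)
        lat[15] = 27.0 - 45.0  # ~5000 km single-day excursion
        tr = self._site_track(dates, lon, lat)
        out = geo.filter_positions(tr)
        assert len(out.positions) == 29
        assert np.allclose(out.positions["lat"], 27.0)


class TestSmoothing:
    def _track(self, lon, lat, start="2010-07-01"):
        dates = pd.date_range(start, periods=len(lon), freq="D")
        df = pd.DataFrame({"date": dates, "lon": lon, "lat": lat})
        return truth_positions_as_track(df, (-15.78, 27.84))

    def test_collinear_equally_spaced_is_fixed_point(self):
        lon = np.linspace(0, 29, 30)
        lat = np.linspace(10, 39, 30)
        out = geo.smooth_track(self._track(lon, lat))
        assert np.allclose(out.positions["lon"], lon, atol=1e-9)
        assert np.allclose(out.positions["lat"], lat, atol=1e-9)

    def test_zigzag_outlier_shrinks_monotonically(self):
        lat = np.full(11, 20.0)
        lat[5] = 24.0
        dev1 = abs(geo.smooth_track(self._track(np.zeros(11), lat), passes=1)
                   .positions["lat"].iloc[5] - 20.0)
        dev2 = abs(geo.smooth_track(self._track(np.zeros(11), lat), passes=2)
                   .positions["lat"].iloc[5] - 20.0)
        assert dev2 < dev1 < 4.0

    def test_white_noise_variance_decreases_each_pass(self):
        rng = np.random.default_rng(7)
        lon = rng.normal(0, 1, 100)
        lat = rng.normal(20, 1, 100)
        v_prev = np.var(lat)
        for passes in (1, 2):
            out = geo.smooth_track(self._track(lon, lat), passes=passes)
            v = np.var(out.positions["lat"].iloc[1:-1])
            assert v < v_prev
            v_prev = v

    def test_below_three_positions_unchanged_with_warning(self):
        tr = self._track(np.array([0.0, 1.0]), np.array([10.0, 11.0]))
        with pytest.warns(UserWarning):
            out = geo.smooth_track(tr)
        assert np.allclose(out.positions["lon"], [0.0, 1.0])
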