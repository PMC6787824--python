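"""Light-level geolocation round trip at a known colony.

Simulates 40 days of clipped logger light at the Veneguera colony, detects
twilights with the threshold-20 rule, calibrates the sun elevation angle
against the known site, and inverts twilight pairs back to positions.
"""

import numpy as np
import pandas as pd

from seaseg import geolocation as geo
from seaseg.space_use import great_circle_km
from seaseg.synthetic_data import SimulationConfig, simulate_light

COLONY = (-15.78, 27.84)  # Veneguera, Gran Canaria
TRUE_ANGLE = -4.5         # sun elevation matching the light threshold

cfg = SimulationConfig(seed=11, twilight_angle_deg=TRUE_ANGLE)
dates = pd.date_range("2010-07-01", periods=40, freq="D")
site = pd.DataFrame({"date": dates, "lon": COLONY[0], "lat": COLONY[1]})
light = simulate_light(site, cfg, np.random.default_rng(11))

twilights = geo.detect_twilights(light, threshold=20)
cal = geo.calibrate_sun_angle(twilights, COLONY, (dates[0], dates[7]))
positions = geo.positions_from_twilights(twilights, cal.sun_angle_deg)
err_km = great_circle_km(positions["lon"], positions["lat"], *COLONY)

print(f"twilight events detected : {len(twilights)}")
print(f"calibrated sun angle     : {cal.sun_angle_deg:+.2f} deg (truth {TRUE_ANGLE:+.2f})")
print(f"median position error    : {np.nanmedian(err_km):.1f} km")
print("A few km of residual error is the floor set by the 10-min recording "
      "interval; real tracks carry ~186 km from shading and behaviour.")
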