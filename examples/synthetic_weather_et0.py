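"""Generate synthetic Mediterranean weather and compare the three
reference-evapotranspiration estimators on a mid-July week."""

import dataclasses

from dripfert.et0 import ET0Params, et0_series
from dripfert.weather import synth_weather

series = synth_weather(years=1, seed=7)
week = [d for d in series if 196 <= d.julian_day <= 202]

params = ET0Params()  # Foggia-like site: 41.46 N, 76 m
pm = et0_series(week, dataclasses.replace(params, method="pm"))
pt = et0_series(week, dataclasses.replace(params, method="pt"))
hs = et0_series(week, dataclasses.replace(params, method="hs"))

print("JD   Tmin  Tmax   Rs    PM    PT    HS   (ET0 in mm/day)")
for d, a, b, c in zip(week, pm, pt, hs):
    print(f"{d.julian_day:3d} {d.tmin:5.1f} {d.tmax:5.1f} {d.solar_rad:5.1f} "
          f"{a:5.2f} {b:5.2f} {c:5.2f}")
# PM is the reference; PT (radiation-driven, alpha = 1.26 default) and HS
# (temperature-only) bracket it until they are locally calibrated —
# see calibrate_et0.py for the calibration that closes the gap.
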