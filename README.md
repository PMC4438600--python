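# dripfert

A decision-support engine for **drip fertigation** of open-field vegetable
crops: a daily coupled water and nitrogen balance that tells a grower *when*
to irrigate, *how much* water to apply, and *how much* N fertilizer to
dissolve in it — including the budget arithmetic required inside EU
nitrate-vulnerable zones (NVZ), where annual N inputs are capped at
170 kg ha⁻¹.

It is written for agronomists and irrigation engineers who want a scriptable
engine (Python API first, a thin `dripfert` CLI for the common shell
workflows) rather than a GUI.

## The model in brief

* **Crop growth** — shoot dry weight follows a logistic curve in thermal
  time, SDW = β₁ / (1 + e^(β₂+β₃t)), with t accumulated as growing degree
  days GDD = max(0, (Tmax+Tmin)/2 − T_base). Hot days scale the day's GDD by
  a linear stress factor between T_M1 and T_M2; hot days during flowering of
  fruit crops permanently lower β₁; a mid-season observed-SDW check rescales
  T_M2 and β₁ from the observed/predicted ratio.
* **Reference ET** — FAO-56 Penman–Monteith, or the Priestley–Taylor
  (α·s/(s+γ)·(Rn−G)/λ) and Hargreaves–Samani
  (C_H (Tmax−Tmin)^E_H (Tmean+C_T) Ra) models after **local calibration**:
  α and E_H are fitted per year by least squares on cumulative ET₀ against
  PM inside a season window, and the multi-year mean is adopted.
* **Crop ET** — dual (Kcb + Ke) or single Kc, with Kcb applied over the
  canopy-covered fraction and Ke over the wetted-bulb surface; plastic
  mulch reduces Ke by 65 % and raises Kcb by 20 % (defaults).
* **Soil water** — wet bulbs under the emitters are truncated ellipsoids
  sized by the Schwartzman–Zur power laws (Xf ∝ Vw^0.22 (Ks/q)^−0.17,
  Zf ∝ Vw^0.63 (Ks/q)^0.45) and rescaled so the wetted volume sits at field
  capacity; plant-available water lives in the intersection of the bulbs
  with a half-ellipsoid effective root volume, integrated on a 1 cm voxel
  grid. Storm runoff uses the SCS curve number; redistribution between
  bulb and root zone uses van Genuchten–Mualem hydraulics.
* **Nitrogen** — crop demand from the critical dilution curve
  (%N = a·SDW^−b, cumulative uptake 10·a·SDW^(1−b)); soil organic matter
  mineralizes at a Hénin–Dupuis-type rate driven by clay, carbonate and
  temperature; root growth intercepts the pre-season mineral stock;
  drainage leaches the dissolved pool. Fertigation doses are the forecast
  net demand scaled by a stage coefficient (1.2 / 2.5 / 0.7 / 0.3 / 0).
* **Engine** — a fixed daily stage order combines the above into a
  pre-season plan (on multiannual-mean temperatures, rain = 0) or
  day-to-day management; in an NVZ the plan checks the N demand against
  the remaining budget and, when infeasible, recomputes the attainable
  biomass by inverting the uptake curve.

A seeded synthetic-weather generator (Mediterranean coastal-plain
climatology) drives everything without any station downloads.

## Worked example

`examples/calibrate_et0.py` calibrates the two low-input ET₀ models against
Penman–Monteith on five synthetic years and evaluates them on a sixth:

```
Hargreaves E_H: per-year optima 0.501, 0.504, 0.505, 0.503, 0.502 -> adopted 0.503
  %RMSE vs PM over the calibration years: 3.52% before, 3.41% after
Priestley-Taylor alpha: per-year optima 1.238, 1.250, 1.249, 1.244, 1.245 -> adopted 1.245
  %RMSE vs PM over the calibration years: 4.40% before, 4.47% after
year-6 daily %RMSE vs PM: HS 3.70%, PT 4.90%
```

The adopted coefficients sit at the canonical values (E_H ≈ 0.50,
α ≈ 1.26), and on the held-out year both calibrated models track PM within
5 % daily RMSE over the 10 Jun – 20 Sep window — temperature-only (HS) or
temperature-plus-radiation (PT) records are enough to run the water
balance on a farm without a full weather station.

`examples/preseason_schedule.py` shows the other half of the story:

```
non-NVZ plan: 115 fertigation events, 14847 m3/ha water, 33.0 kg/ha N, final SDW 4.23 t/ha
NVZ plan:     115 events, 8.9 kg/ha N (budget 20), final SDW 1.73 t/ha
  attainable biomass recapped from 6.0 to 2.44 t/ha by the N ceiling
```

With only 20 kg ha⁻¹ of NVZ budget left, the engine refuses to plan the
full yield, recaps the attainable biomass from the available N and keeps
the season inside the legal ceiling.

The other examples cover soil hydraulics (`soil_hydraulics.py`), the
weather generator and estimator comparison (`synthetic_weather_et0.py`)
and the growth model with heat stress and the SDW check
(`growth_curve.py`). The same workflows are available from the shell:

```bash
dripfert synth-weather --years 5 --seed 1 --out meteo.csv
dripfert calibrate-et0 --method hs --years meteo.csv --window 161:263
dripfert preseason --config sector.yaml --meteo meteo.csv --out schedule.csv
```

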