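# Methods

This note documents the models, the numerical choices, and what the
synthetic test bed does and does not establish.

## Crop growth

Shoot dry weight (SDW, t ha⁻¹) follows SDW(t) = β₁/(1+e^(β₂+β₃t)) in
thermal time t (°C d), with daily GDD = max(0, (Tmax+Tmin)/2 − T_base).
β₁ can be derived from the expected fresh yield as
Exp_yld·YldDW/100/HI·n_plant (g ha⁻¹ → t ha⁻¹). Operation order within a
day is a deliberate contract: heat stress first scales the day's GDD
(linearly from 1 at T_M1 to 0 at T_M2), the potential gain is then the
increment of the current logistic curve, and water stress finally scales
that gain. When β₁ or T_M2 change (flowering heat or the SDW check), the
curve is rescaled, not refit: gains stay incremental, so the simulated SDW
trajectory is continuous.

Flowering heat days multiply the running β₁ by 1 − (Tmax−Flw_Tmax)/Flw_dur
and compound across days (the replacement is permanent). The penalty
divides a temperature excess (°C) by a duration (°C d); dimensionally odd
but implemented as printed in the source formulation of this rule.

Water stress: stress applies when the readily available water remaining in
the wet root zone cannot cover the day's crop demand on that store. The
implemented loss fraction is k_y·ETc_L/(TAW−RAW), where ETc_L is the part
of the demand beyond the readily available water, clamped to the stress
buffer. This monotone form (worse as the soil dries; loss → k_y at total
depletion) replaces a literal transcription whose loss vanishes at total
depletion; the literal form is available behind `literal_eq7` for
comparison. ETc_L itself has no printed formula; we define it as
max(0, demand − readily available water today).

Maturity: non-fruit crops mature at the thermal sum TS_min. Fruit crops
need `d_SDWstop` *consecutive* positive-GDD days with relative SDW growth
below 0.4 % (the counter resets on any other day), plus TS_min; TS_max
forces maturity unconditionally.

Plantlet alignment: lighter-than-reference transplants are held in a lag
phase at `Plts_GR` g day⁻¹ until they reach `Plts_Ref`; heavier ones start
the curve at the thermal time whose SDW matches the observed per-hectare
stand (zero if the curve's origin already exceeds it).

## Reference and crop evapotranspiration

Penman–Monteith follows FAO-56 exactly (daily step, G = 0, reference
albedo 0.23, net longwave from Rs/Rso with the clear-sky fraction capped
at 1, e_a from RHmax/RHmin or e°(Tmin) when humidity is absent); the
implementation reproduces the FAO-56 daily worked example (Uccle, 6 July:
3.88 mm) to the printed precision. Priestley–Taylor uses the configurable
crop albedo (default 0.24) in its net radiation and floors negative
available energy at zero. Hargreaves–Samani converts extraterrestrial
radiation to equivalent evaporation (Ra/λ, λ = 2.45 MJ kg⁻¹) — the
formula is sometimes printed with Ra in energy units; the conversion is
required for mm day⁻¹ output.

Calibration minimizes the SSE between *cumulative* ET₀ curves (candidate
vs PM) inside a julian-day window, per year, by bounded Brent search
(E_H ∈ [0.3, 0.8], α ∈ [0.5, 2.6], tolerance 1e-6); the adopted value is
the mean of per-year optima. Fit quality is reported as %RMSE of *daily*
values (100·RMSE/mean of the reference): the objective and the report are
deliberately different statistics.

Crop ET uses the dual coefficient by default: transpiration Kcb·ET₀ over
the canopy-covered fraction (the smaller of the stage soil-cover
percentage and the effective-root-volume top area), evaporation Ke·ET₀
over the bulb top-surface fraction. Mulch multiplies Ke by 0.35 and Kcb
by 1.20 (defaults) and sheds rain off the beds.

## Soil water

Pedotransfer: nine published texture regressions estimate θ_FC and θ_WP;
the Saxton form is the default and also yields θ_sat and BD = (1−sat)·2.65.
The retention-shape constants (θ_r, α, n) and default Ks come from the
Carsel & Parrish (1988) USDA-class means. A texture sweep shows the
Manrique regression (method 3) inverts FC and WP for heavy clays at high
bulk density; the package asserts the ordering everywhere else and leaves
that documented corner to the user. Conductivity uses
K = Ks·S·[1−(1−S^(1/m))]² as the working form (a flag switches to the
standard Mualem K = Ks·√S·[1−(1−S^(1/m))^m]²).

Wet bulbs: the Schwartzman–Zur power laws give the wetted width and depth
from the applied volume per emitter, Ks (converted cm d⁻¹ → m s⁻¹) and
the emitter discharge; the bulb is then rescaled so the wetted volume
sits at field capacity. In the rescale identity the horizontal dimension
acts as a *semi-axis*: (2/3)π·Xf1²·Zf1·θ_FC = Vw holds exactly under that
reading, which the package adopts (the pre-rescale Xf is a diameter).

Wet root volume: the per-plant sum of voxel-integrated intersections
(1 cm grid, fixed traversal) between each bulb and the half-ellipsoid
root volume, without union correction — overlapping bulbs are counted
per-bulb, matching the sum-of-interactions bookkeeping. The grid agrees
with a 10⁶-point Monte-Carlo oracle within 2 % across randomized
geometries.

Water accounting uses two lumped reservoirs plus an inert term, all in
m³ ha⁻¹: plant-available water in the effective root volume (capacity
(θ_FC−θ_WP)·ERV, refill target TAW = (θ_FC−θ_WP)·WRV), available water in
the bulbs outside the root volume, and below-wilting-point water bound in
newly wetted soil. The irrigation trigger compares the root-zone
depletion with RAW = p·TAW (p ∈ [0.20, 0.50]); day 0 always irrigates;
the ripening phase of fruit crops never does. The phase rules size the
dose geometrically (establishment: bulb radius reaching the neighbouring
plants' root-zone centers, worst case half the emitter spacing; root
deepening: bulb depth = current root depth; full root: bulb depth =
maximum root depth), floored at the store deficit. Non-NVZ surpluses
drain the same day and carry dissolved N; in an NVZ the bulb depth is
capped at the maximum root depth and the recommended volume is reduced by
the antecedent-moisture credit so fertigation never drains — only rain
can leach. A consequence of the literal geometric dosing is that full-root
events on zero-rain (pre-season) weather can exceed the deficit
substantially; the NVZ mode shows the trimmed alternative.

Redistribution between bulbs and root zone follows
q = (K(θ̄)/Ks)·(S₁−S₂)·(θ_s−θ_r)·Ve per day — the printed form mixes a
velocity with a volume, so the package reads it as "relative conductivity
× saturation gradient = fraction of the wetted root-zone volume
transferred per day", capped so one step never inverts the gradient.
Water gained by root growth into unwetted soil (Q_add) is the newly
explored volume times a background moisture level (default halfway
between WP and FC, configurable), since no sub-model is printed for it.

The daily ledger closes by construction and is asserted in the tests:
Δ(storage) = irrigation + stored rain + Q_add − ETc − drainage to better
than 10⁻⁶ of TAW every simulated day. Rain is credited over the
root-zone footprint fraction only; the remainder falls outside the
modeled volume.

## Nitrogen

Crop uptake follows the critical dilution curve: %N = a·SDW^−b with a
plateau at `a` below 1 t ha⁻¹ (the power law diverges at zero biomass),
and cumulative uptake N_upt = 10·a·SDW^(1−b). Daily uptake is the
increment of that curve, limited by the mineral pool; the transplants'
own N (the curve evaluated at the initial stand) is drawn from the pool
on day 0 so the season-end cumulative uptake equals the curve exactly.

Mineralization: k₂ = [1200/((clay+200)(0.3·CaCO₃+200))]·max(0, T/2−5)
yr⁻¹ — the temperature term is read as a multiplier (consistent with the
Hénin–Dupuis lineage; an all-denominator literal reading is available
behind a flag) and clamps to zero at 10 °C. Daily release is
(Soil_wt·N_org/1000·k₂·P)/365 with Soil_wt the ERV soil mass capped at
the plough-depth mass, and P = f_r·I·Ts the management product
(f_r from the residue/organic-input grid, I = 1.25, Ts ∈ {1.0, 0.8, 0.5}).

Interception credits the pre-season NO₃+NH₄ stock contained in each
day's newly explored root volume; summed over the season it telescopes to
the stock of the final root volume and stops once roots reach their
maxima. Leaching removes the dissolved pool in proportion to the drained
fraction of stored water. Atmospheric deposition and gaseous losses are
both omitted (assumed to cancel).

Fertigation doses trigger when the pool falls below the stage threshold
(the three thresholds are aligned to the Kc phase days T1/T3, which the
source leaves implicit) and equal the forecast uptake to the next
presumable irrigation (horizon = RAW/ETc days, 1–10) net of forecast
mineralization and interception, scaled by K_Nrate (1.2 ≤T1, 2.5 ≤T2,
0.7 first 60 % of the mid phase, 0.3 rest, 0 after T3). Doses ride on
irrigation events only. The NVZ budget (170 − N_year − pre-planting N)
caps every dose; feasibility is checked in the pre-season plan and, when
the unconstrained demand exceeds the budget, the attainable biomass is
recomputed as SDW = (N_avail/(10a))^(1/(1−b)) with N_avail = budget +
forecast mineralization + intercepted stock, and the season re-simulated.

## Synthetic weather

The generator emulates a Mediterranean coastal plain at 41.46° N / 76 m:
annual temperature waves (Tmax 22 ± 10.5 °C, Tmin 10.5 ± 7.5 °C, peak late
July) with a shared AR(1) anomaly; two-state Markov rainfall peaking in
winter with gamma amounts; solar radiation as extraterrestrial radiation
times a transmissivity of 0.72 ± 0.02 on dry days (near-cloudless summer)
and 0.45 ± 0.10 on wet days; humidity from a dewpoint tracking Tmin minus
a seasonal depression; a light breeze regime (median ≈ 1.2–2 m s⁻¹,
σ_log = 0.10) peaking with the summer heat. The fluctuations are
physically coupled — clearer days widen the diurnal range, warm advective
spells are windier and drier — because that coherence between radiative
and aerodynamic drivers is what makes a single locally calibrated
coefficient (E_H or α) track Penman–Monteith through a summer window;
at sites with strong independent wind and cloud variability the same
calibration would do worse, and the tests say nothing about such sites.
Under these conditions the calibrations land on E_H ≈ 0.50 and α ≈ 1.25,
the canonical literature values.

What passing the synthetic tests shows: internal consistency (ledgers
close, geometry integrates correctly, calibrations recover planted
coefficients, the logistic asymptote is reached without stress) and
climate-plausible behaviour. What it does not show: predictive skill on
real fields, which requires station weather and measured soil and crop
parameters.

## Problem sizes and numerics

Test and acceptance runs use 6 synthetic years for calibration work,
120–160-day seasons for the engine, a 1 cm voxel grid for geometry
(10⁶-point Monte Carlo as oracle), Brent tolerance 1e-6 for calibration
and 1e-10 m³ for bulb-volume inversion. Texture sums tolerate ±0.5 %
with renormalization. Exponential overflow in the logistic is guarded at
exponent 700. All engine state is deterministic; the only randomness in
the package is the seeded weather generator.

## Known limitations

One homogeneous soil layer (no hysteresis, no capillary rise, no layered
profiles); no mechanistic photosynthesis; no gap-filling of real weather
data; no sub-daily time step; the redistribution rule is an admitted
approximation, not a Richards solver; fertilizer is assumed fully and
immediately available; per-plant intersection sums can double-count
overlapping bulbs by design.
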