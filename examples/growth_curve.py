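"""The thermal-time logistic growth model: heat stress, an in-season
SDW check, and the maturity rules."""

from dripfert.growth import (
    CropGrowthParams, GrowthState, gdd, logistic_sdw, sdw_check,
    thermal_stress_coeff,
)

crop = CropGrowthParams(
    beta1=6.0, beta2=5.0, beta3=-0.005, t_base=10.0, t_m1=35.0, t_m2=45.0,
    k_sdw1=1.0, k_sdw2=0.5, k_t3=45.0,
)

# a mild day and a heat-stress day
for tmax, tmin in ((29.0, 17.0), (39.0, 22.0)):
    g = gdd(tmax, tmin, crop.t_base)
    k = thermal_stress_coeff(tmax, crop.t_m1, crop.t_m2)
    print(f"Tmax {tmax:.0f}: GDD {g:.1f} deg-C-d, heat-stress factor {k:.2f}, "
          f"effective {g * k:.1f}")

# the logistic curve: inflection at -beta2/beta3 = 1000 deg-C-d
for tt in (200, 600, 1000, 1600, 2200):
    print(f"  thermal time {tt:4d} -> SDW {logistic_sdw(tt, 6.0, 5.0, -0.005):.2f} t/ha")

# mid-season check: the crop is 20 % ahead of the prediction
state = GrowthState(sdw=2.0, beta1_current=6.0, t_m2_current=45.0)
new_tm2, new_beta1 = sdw_check(state, sdw_observed=2.4, params=crop)
print(f"SDW check (observed/predicted = 1.2): "
      f"beta1 {6.0:.1f} -> {new_beta1:.2f} t/ha (curve rescaled upward)")
# A ratio above 1 rescales the attainable biomass by K_SDW1*rho^K_SDW2;
# the subsequent N demand follows the larger curve.
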