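"""Classify a soil, estimate its hydraulic constants, and evaluate the
retention/conductivity functions the redistribution step relies on."""

from dripfert.soil import (
    SoilTexture, classify_usda, default_hydraulics, hydraulic_conductivity,
    pedotransfer, relative_saturation,
)

# a lab report: 40 % sand, 30 % silt, 30 % clay, 2 % organic matter
texture = SoilTexture(sand=40, silt=30, clay=30, organic_matter=2.0)

print("USDA class:", classify_usda(texture))

est = pedotransfer(texture, method=9)  # Saxton regression (the default)
print(f"pedotransfer: theta_FC = {est['theta_fc']:.3f} m3/m3, "
      f"theta_WP = {est['theta_wp']:.3f} m3/m3, BD = {est['bulk_density']:.2f} g/cm3")

hyd = default_hydraulics(texture)  # + Carsel-Parrish class defaults (Ks, alpha, n)
print(f"Ks = {hyd.ks} cm/d, van Genuchten alpha = {hyd.vg_alpha} 1/cm, n = {hyd.vg_n}")

theta = 0.5 * (hyd.theta_fc + hyd.theta_wp)
s = relative_saturation(theta, hyd)
k = hydraulic_conductivity(theta, hyd)
print(f"halfway between WP and FC (theta = {theta:.3f}): "
      f"S = {s:.3f}, K = {k:.4f} cm/d")
# S is the relative saturation driving bulb-to-root-zone redistribution;
# K collapses quickly below field capacity, which is why the daily
# redistribution flux matters most right after an irrigation.
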