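"""Pre-season fertigation plan for a tomato-like sector, with and without
the nitrate-vulnerable-zone (NVZ) budget."""

import dataclasses

from dripfert.engine import SectorConfig, run_preseason
from dripfert.soil import SoilChemistry
from dripfert.weather import multiannual_mean, synth_weather

# multiannual-mean temperatures (rain forced to zero), transplant ~1 May
mean = multiannual_mean(synth_weather(years=5, seed=9))
season = mean.window(121, 330)

# low-fertility soil so fertilizer is actually demanded
config = SectorConfig(
    chemistry=SoilChemistry(som=10.0, n_org=0.5, no3_n=3.0, nh4_n=1.0, caco3=80.0),
    n_min_res_1=25.0, n_min_res_2=40.0, n_min_res_3=15.0,
)

plan = run_preseason(config, season)
t = plan.season_totals
print(f"non-NVZ plan: {len(plan.events)} fertigation events, "
      f"{t['irrigation_net_m3_ha']:.0f} m3/ha water, "
      f"{t['n_applied_kg_ha']:.1f} kg/ha N, final SDW {t['final_sdw_t_ha']:.2f} t/ha")

# the same sector inside an NVZ that already received 150 kg/ha this year:
# only 20 kg/ha of budget remain, so the plan recaps the attainable yield
nvz_config = dataclasses.replace(config, nvz=True, n_year=150.0)
nvz_plan = run_preseason(nvz_config, season)
t = nvz_plan.season_totals
print(f"NVZ plan:     {len(nvz_plan.events)} events, "
      f"{t['n_applied_kg_ha']:.1f} kg/ha N (budget 20), "
      f"final SDW {t['final_sdw_t_ha']:.2f} t/ha")
if nvz_plan.recapped_beta1 is not None:
    print(f"  attainable biomass recapped from {config.crop.beta1:.1f} to "
          f"{nvz_plan.recapped_beta1:.2f} t/ha by the N ceiling")
# In an NVZ the engine never schedules more N than the 170 kg/ha/yr cap
# allows, and irrigation volumes are trimmed so no drainage (hence no
# nitrate leaching) occurs from fertigation events.
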