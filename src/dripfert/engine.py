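"""Daily fertigation engine: configuration, the simulation loop and outputs.

Two operating modes share one daily step:

* **pre-season plan** — a full-season simulation on multiannual-mean
  temperatures (rain forced to zero) that emits the expected schedule of
  fertigation events; in a nitrate-vulnerable zone (NVZ) it first checks
  whether the planned N demand fits the 170 kg/ha/yr ceiling and, if not,
  recaps the attainable biomass by inverting the N-uptake curve and
  re-simulates;
* **day-to-day management** — the same step driven by observed weather,
  with recommended events confirmed, modified or declined by the user.

The daily step applies a fixed stage order: (1) thermal time with heat
stress, (2) root advance with the water and mineral-N gains of the newly
explored soil, (3) rain infiltration and runoff, (4) reference and crop ET
extraction, (5) bulb-to-root-zone redistribution, (6) water-stress-corrected
growth increment, (7) SOM mineralization and N uptake, (8) leaching on
drainage, (9) the irrigation decision, (10) the fertigation dose,
(11) the maturity check.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml

from . import growth as gr
from . import nitrogen as ni
from . import water as wa
from .et0 import ET0Params, et0_series
from .soil import SoilChemistry, SoilHydraulics, SoilTexture, default_hydraulics
from .weather import WeatherDay, WeatherSeries

__all__ = [
    "PlantLayout",
    "SectorConfig",
    "DailyRecord",
    "FertigationSchedule",
    "SimulationState",
    "run_preseason",
    "run_inseason",
    "step_day",
    "apply_sdw_check",
    "write_schedule",
    "read_schedule",
]

MM_TO_M3_HA = wa.MM_TO_M3_HA


@dataclass
class PlantLayout:
    """Row/emitter geometry (cm) and arrangement."""

    in_row: float = 35.0  # plant-to-plant spacing
    bet_rows: float = 150.0  # row spacing (= drip line spacing here)
    bet_twins: float = 40.0  # distance between the two rows of a twin pair
    pl_arr: Literal["single", "twin"] = "single"

    @property
    def nplant(self) -> float:
        per_line = 1e4 / ((self.bet_rows / 100.0) * (self.in_row / 100.0))
        return per_line * (2.0 if self.pl_arr == "twin" else 1.0)


@dataclass
class SectorConfig:
    """Everything the engine needs for one fertigation sector.

    Groups the sector-setup entries: site, soil (texture, chemistry,
    hydraulics), crop calibration, Kc trajectory, irrigation hardware,
    N options and runoff.  ``materialize()`` fills the auto-suggested
    soil hydraulics from the pedotransfer routine so a saved config is
    self-describing.
    """

    sector_id: str = "sector-1"
    latitude_deg: float = 41.46
    elevation_m: float = 76.0
    nvz: bool = False
    texture: SoilTexture = field(default_factory=lambda: SoilTexture(sand=40, silt=30, clay=30))
    chemistry: SoilChemistry = field(
        default_factory=lambda: SoilChemistry(som=20.0, n_org=1.2, no3_n=10.0, nh4_n=2.0, caco3=50.0)
    )
    hydraulics: Optional[SoilHydraulics] = None
    pedotransfer_method: int = 9
    layout: PlantLayout = field(default_factory=PlantLayout)
    crop: gr.CropGrowthParams = field(
        default_factory=lambda: gr.CropGrowthParams(
            beta1=6.0, beta2=5.0, beta3=-0.005, t_base=10.0, t_m1=35.0, t_m2=45.0,
            flw_beg=450.0, flw_dur=300.0, flw_tmax=36.0, ky_b=0.8,
            ts_min=1400.0, ts_max=2300.0, d_sdwstop=5,
            plts_ref=1.0, plts_gr=0.1, exp_yld=2000.0, yld_dw=6.0, hi=0.6,
        )
    )
    kc: wa.KcProfile = field(default_factory=wa.KcProfile)
    hardware: wa.IrrigationHardware = field(default_factory=wa.IrrigationHardware)
    et0: ET0Params = field(default_factory=ET0Params)
    ncurve: ni.NCurveParams = field(default_factory=lambda: ni.NCurveParams(a=4.5, b=0.33))
    mineralization: ni.MineralizationParams = field(default_factory=ni.MineralizationParams)
    raw_pct: float = 0.35  # readily available fraction of TAW (0.20-0.50)
    curve_number: float = 75.0
    pre_n: float = 0.0  # pre-planting N, kg/ha
    irrwt_n: float = 0.0  # nitrate-N in irrigation water, ppm
    n_year: float = 0.0  # N already applied this year on the same soil, kg/ha
    n_min_res_1: float = 20.0  # kg/ha trigger thresholds by stage
    n_min_res_2: float = 30.0
    n_min_res_3: float = 15.0
    plts_dw: float = 1.0  # plantlet mass at transplant, g
    establishment_days: int = 12
    background_moisture_frac: float = 0.5  # of (FC-WP), feeds Qadd
    literal_eq7: bool = False

    def __post_init__(self) -> None:
        if not 0.20 <= self.raw_pct <= 0.50:
            raise ValueError("raw_pct must be within 0.20-0.50")
        # the crop density follows from the layout
        self.crop.nplant = self.layout.nplant
        self.et0.latitude_deg = self.latitude_deg
        self.et0.elevation_m = self.elevation_m

    def materialize(self) -> "SectorConfig":
        """Fill auto-suggested hydraulics from texture (provenance: suggested)."""
        if self.hydraulics is None:
            self.hydraulics = default_hydraulics(self.texture, self.pedotransfer_method)
        return self

    @property
    def twin_row_sandy(self) -> bool:
        assert self.hydraulics is not None
        return self.layout.pl_arr == "twin" and "sand" in self.hydraulics.usda_class

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("texture", "chemistry", "hydraulics"):
            obj = getattr(self, key)
            d[key] = obj.model_dump() if obj is not None else None
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SectorConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["texture"] = SoilTexture(**d["texture"])
        d["chemistry"] = SoilChemistry(**d["chemistry"])
        if d.get("hydraulics"):
            d["hydraulics"] = SoilHydraulics(**d["hydraulics"])
        d["layout"] = PlantLayout(**d["layout"])
        d["crop"] = gr.CropGrowthParams(**d["crop"])
        d["kc"] = wa.KcProfile(**d["kc"])
        d["hardware"] = wa.IrrigationHardware(**d["hardware"])
        d["et0"] = ET0Params(**d["et0"])
        d["ncurve"] = ni.NCurveParams(**d["ncurve"])
        d["mineralization"] = ni.MineralizationParams(**d["mineralization"])
        return cls(**d)


@dataclass
class Confirmation:
    """User feedback on the day's recommendation (in-season mode)."""

    irrigation: bool = True
    volume_net: Optional[float] = None  # m3/ha actually delivered, if different
    n_dose: Optional[float] = None  # kg/ha actually injected, if different


@dataclass
class DailyRecord:
    dat: int
    julian_day: int
    rain: float
    tmin: float
    tmax: float
    gdd_raw: float
    k_ts: float
    gdd_eff: float
    sdw: float
    thermal_time: float
    et0: float
    etc: float
    transpiration: float
    evaporation: float
    w_erv: float
    w_out: float
    taw: float
    raw: float
    depletion: float
    irrigation_net: float
    irrigation_gross: float
    duration_h: float
    n_dose: float
    n_uptake: float
    nsom: float
    n_interception: float
    n_pool: float
    drainage: float
    runoff: float
    leached: float
    qadd: float
    qrain: float
    redistribution: float
    storage: float
    phase: str
    water_stress: bool
    sdw_check_applied: bool
    nvz_cap_hit: bool
    mature: bool


@dataclass
class FertigationSchedule:
    events: pd.DataFrame  # one row per irrigation/fertigation event
    records: list[DailyRecord]
    season_totals: dict[str, float]
    nvz: bool = False
    nvz_compliant: Optional[bool] = None
    recapped_beta1: Optional[float] = None


@dataclass
class SimulationState:
    """Aggregate state advanced by :func:`step_day`."""

    config: SectorConfig
    growth: gr.GrowthState
    water: wa.WaterState
    nitrogen: ni.NState
    bulbs: list[wa.WetBulb] = field(default_factory=list)
    bulb_dims: tuple[float, float] = (0.0, 0.0)  # current (xf1, zf1)
    records: list[DailyRecord] = field(default_factory=list)
    cum_nupt_curve: float = 0.0  # Eq-28 cumulative tracked alongside the pool
    _geom_cache: dict = field(default_factory=dict)

    @property
    def dat(self) -> int:
        return self.growth.dat


# ---------------------------------------------------------------------------


def _init_state(config: SectorConfig) -> SimulationState:
    config.materialize()
    hyd = config.hydraulics
    assert hyd is not None
    crop = config.crop
    lag, tt0 = gr.align_cycle_to_plantlet(config.plts_dw, crop)
    sdw0 = max(config.plts_dw, crop.plts_ref) * crop.nplant / 1e6
    if tt0 > 0:
        sdw0 = gr.logistic_sdw(tt0, crop.beta1, crop.beta2, crop.beta3)
    gstate = gr.GrowthState(
        thermal_time=tt0,
        sdw=sdw0,
        beta1_current=crop.beta1,
        t_m2_current=crop.t_m2,
        lag_days_left=lag,
        plantlet_mass=config.plts_dw,
    )
    root = gr.advance_roots(0, crop, False)
    v_erv_ha = root.erv * 1e-6 * crop.nplant  # cm3/plant -> m3/ha
    wstate = wa.WaterState(
        v_erv=v_erv_ha,
        cap_erv=(hyd.theta_fc - hyd.theta_wp) * v_erv_ha,
    )
    # background soil supplies a configurable fraction of plant-available water
    wstate.w_erv = config.background_moisture_frac * wstate.cap_erv
    bd = hyd.bulk_density or 1.35
    initial_stock = (config.chemistry.no3_n + config.chemistry.nh4_n) * (
        v_erv_ha * bd * 1000.0
    ) * 1e-6
    nstate = ni.NState(
        soil_mineral_n=initial_stock + config.pre_n,
        cum_applied=config.pre_n,
        cum_interception=initial_stock,
    )
    if config.nvz:
        nstate.nvz_budget_remaining = ni.NVZ_ANNUAL_CAP - config.n_year - config.pre_n
    state = SimulationState(
        config=config, growth=gstate, water=wstate, nitrogen=nstate
    )
    # the transplants arrive carrying the N of their initial biomass
    seed_n = min(ni.n_uptake_cum(sdw0, config.ncurve), nstate.soil_mineral_n)
    nstate.soil_mineral_n -= seed_n
    nstate.cum_uptake += seed_n
    state.cum_nupt_curve = ni.n_uptake_cum(sdw0, config.ncurve)
    return state


def _emitter_positions(config: SectorConfig, reach: float) -> list[tuple[float, float]]:
    ed = config.hardware.emit_dist / 100.0
    xs = [(k + 0.5) * ed for k in range(-4, 4)]
    return [(x, 0.0) for x in xs if abs(x) <= reach]


def _geometry(state: SimulationState, root: gr.RootGeometry) -> tuple[float, float, float]:
    """(V_erv, V_wrv, V_out) in m3/ha for the current root + bulb setup."""
    config = state.config
    crop = config.crop
    r = root.r / 100.0
    r1 = root.r1 / 100.0
    depth = root.depth / 100.0
    y_plant = config.layout.bet_twins / 200.0 if config.layout.pl_arr == "twin" else 0.0
    y_center = y_plant - root.center_offset / 100.0
    v_erv_ha = root.erv * 1e-6 * crop.nplant
    xf1, zf1 = state.bulb_dims
    if xf1 <= 0:
        return v_erv_ha, 0.0, 0.0
    key = (round(r, 4), round(r1, 4), round(depth, 4), round(xf1, 4), round(zf1, 4))
    if key in state._geom_cache:
        v_int_plant = state._geom_cache[key]
    else:
        positions = _emitter_positions(config, reach=r + xf1 + 0.01)
        bulbs = [
            wa.WetBulb(xf1=xf1, zf1=zf1, position=p)
            for p in positions
            if math.hypot(p[0], p[1] - y_center) < r + xf1
        ]
        v_int_plant = wa.wrv_intersection(r, r1, depth, (0.0, y_center), bulbs)
        state._geom_cache[key] = v_int_plant
        if len(state._geom_cache) > 512:
            state._geom_cache.clear()
    v_wrv_ha = min(v_int_plant * crop.nplant, v_erv_ha)
    emitters = config.hardware.emitters_per_ha
    v_bulb_ha = wa.bulb_volume(xf1, zf1) * emitters
    v_out_ha = max(v_bulb_ha - v_wrv_ha, 0.0)
    return v_erv_ha, v_wrv_ha, v_out_ha


def _phase(state: SimulationState) -> str:
    config, g = state.config, state.growth
    crop = config.crop
    if (
        crop.hrvst_type == "ripe_fruit"
        and g.days_low_growth >= 1
        and g.thermal_time >= crop.ts_min
    ):
        return "ripening"
    if g.dat <= config.establishment_days:
        return "establishment"
    if g.dat < crop.root_d_max:
        return "root_deepening"
    return "full_root"


def _establishment_reach(config: SectorConfig, root: gr.RootGeometry) -> float:
    # a bulb must reach the root-zone center of every neighbouring plant;
    # the worst case along the lateral is half the emitter spacing
    half_emit = config.hardware.emit_dist / 200.0
    y_plant = config.layout.bet_twins / 200.0 if config.layout.pl_arr == "twin" else 0.0
    y_center = y_plant - root.center_offset / 100.0
    return math.hypot(half_emit, y_center) + 1e-3


def step_day(
    state: SimulationState,
    day: WeatherDay,
    confirmation: Optional[Confirmation] = None,
) -> DailyRecord:
    """Advance the simulation by one day and append the daily record."""
    config = state.config
    hyd = config.hydraulics
    assert hyd is not None
    crop, g, w, n = config.crop, state.growth, state.water, state.nitrogen
    confirm = confirmation or Confirmation()
    fc_wp = hyd.theta_fc - hyd.theta_wp
    bd = hyd.bulk_density or 1.35

    # (1) thermal time and heat stress ------------------------------------
    gdd_raw = gr.gdd(day.tmax, day.tmin, crop.t_base)
    k_ts = gr.thermal_stress_coeff(day.tmax, crop.t_m1, g.t_m2_current)
    gdd_eff = gdd_raw * k_ts
    in_lag = g.lag_days_left > 0

    # (2) root advance, Qadd and mineral-N interception -------------------
    root = gr.advance_roots(g.dat, crop, config.twin_row_sandy)
    v_erv_prev, v_wrv_prev, v_out_prev = w.v_erv, w.v_wrv, w.v_out
    v_erv, v_wrv, v_out = _geometry(state, root)
    delta_erv = max(v_erv - v_erv_prev, 0.0)
    delta_wrv = max(v_wrv - v_wrv_prev, 0.0)
    capture = 0.0
    if delta_wrv > 0 and v_out_prev > 1e-12:
        capture = min(w.w_out, w.w_out * min(delta_wrv / v_out_prev, 1.0))
        w.w_out -= capture
        w.w_erv += capture
    qadd = max(delta_erv - delta_wrv, 0.0) * config.background_moisture_frac * fc_wp
    w.w_erv += qadd
    w.cum_qadd += qadd
    w.v_erv, w.v_wrv, w.v_out = v_erv, v_wrv, v_out
    w.cap_erv = fc_wp * v_erv
    w.taw = fc_wp * v_wrv
    w.raw = config.raw_pct * w.taw
    w.cap_out = fc_wp * v_out
    overflow = max(w.w_out - w.cap_out, 0.0)
    w.w_out -= overflow
    w.w_erv += overflow
    drainage = max(w.w_erv - w.cap_erv, 0.0)
    w.w_erv -= drainage
    intercepted = ni.n_interception(
        delta_erv, config.chemistry.no3_n, config.chemistry.nh4_n, bd
    )
    n.soil_mineral_n += intercepted
    n.cum_interception += intercepted

    # (3) rain: runoff, infiltration over the root-zone footprint ---------
    runoff_mm = 0.0
    qrain = 0.0
    if day.rain > 0.0:
        if config.kc.mulch:
            runoff_mm = day.rain  # film sheds rain off the beds
        else:
            runoff_mm = wa.runoff_cn(day.rain, config.curve_number)
        erv_top_frac = min(
            crop.nplant * math.pi * (root.r / 100.0) * (root.r1 / 100.0) / 1e4, 1.0
        )
        deficit = (w.cap_erv - w.w_erv) + (w.cap_out - w.w_out)
        res = wa.effective_rain(
            (day.rain - runoff_mm) * erv_top_frac, 0.0, deficit
        )
        qrain = res["qrain"]
        drainage += res["drainage"]
        to_erv = min(qrain, w.cap_erv - w.w_erv)
        w.w_erv += to_erv
        w.w_out += qrain - to_erv
        w.cum_rain_stored += qrain
        w.cum_runoff += runoff_mm * MM_TO_M3_HA
    raw_available = max(w.w_erv - (w.taw - w.raw), 0.0)

    # (4) reference and crop ET, extraction -------------------------------
    et0 = float(et0_series([day], config.et0)[0])
    kcs = wa.kc_interpolate(min(g.dat, config.kc.t4), config.kc)
    erv_top_frac = min(
        crop.nplant * math.pi * (root.r / 100.0) * (root.r1 / 100.0) / 1e4, 1.0
    )
    covered = min(kcs["soil_cover_fraction"], erv_top_frac)
    xf1, zf1 = state.bulb_dims
    wet_frac = min(
        config.hardware.emitters_per_ha * math.pi * xf1**2 / 1e4, 1.0
    ) if xf1 > 0 else 0.0
    split = wa.etc_dual(
        et0, kcs["kcb"], kcs["ke"], covered, wet_frac,
        mode=config.kc.mode, kc=kcs["kc"],
    )
    etc_v = split["etc"] * MM_TO_M3_HA
    evap_v = split["evaporation"] * MM_TO_M3_HA
    transp_v = split["transpiration"] * MM_TO_M3_HA
    e_from_out = min(evap_v, w.w_out)
    w.w_out -= e_from_out
    demand_erv = transp_v + (evap_v - e_from_out)
    from_erv = min(demand_erv, w.w_erv)
    w.w_erv -= from_erv
    etc_actual = e_from_out + from_erv
    w.cum_etc += etc_actual
    # crop water stress is judged on the demand placed on the root-zone store
    crop_demand_v = demand_erv

    # (5) redistribution from the bulbs into the root zone ----------------
    redis = 0.0
    if w.v_out > 1e-9 and w.v_wrv > 1e-9:
        theta_out = hyd.theta_wp + w.w_out / w.v_out
        theta_erv = hyd.theta_wp + w.w_erv / w.v_erv
        clamp = lambda t: min(max(t, hyd.theta_res + 1e-9), hyd.theta_sat)
        s1 = wa.relative_saturation(clamp(theta_out), hyd)
        s2 = wa.relative_saturation(clamp(theta_erv), hyd)
        flux = wa.redistribution_flux(
            s1, s2, clamp(0.5 * (theta_out + theta_erv)), hyd, w.v_wrv
        )
        if flux > 0:
            redis = min(flux, w.w_out, w.cap_erv - w.w_erv)
            w.w_out -= redis
            w.w_erv += redis
        else:
            back = min(-flux, w.w_erv, w.cap_out - w.w_out)
            w.w_erv -= back
            w.w_out += back
            redis = -back
        w.cum_redistribution += redis

    # (6) growth increment with water-stress correction -------------------
    stressed = False
    sdw_gain = 0.0
    if in_lag:
        g.plantlet_mass += crop.plts_gr
        g.lag_days_left -= 1
        gdd_eff = 0.0
    elif not g.mature:
        b1 = g.beta1_current
        if b1 > 0:
            sdw_m = gr.logistic_sdw(g.thermal_time + gdd_eff, b1, crop.beta2, crop.beta3) - \
                gr.logistic_sdw(g.thermal_time, b1, crop.beta2, crop.beta3)
            sdw_m = max(sdw_m, 0.0)
            if raw_available < crop_demand_v and w.taw > w.raw:
                stressed = True
                sdw_gain = gr.water_stress_sdw(
                    sdw_m, crop_demand_v, raw_available, w.taw, w.raw, crop.ky_b,
                    literal_eq7=config.literal_eq7,
                )
            else:
                sdw_gain = sdw_m
        g.thermal_time += gdd_eff
        # hot flowering days permanently lower the asymptote (fruit crops)
        if (
            crop.hrvst_type == "ripe_fruit"
            and crop.flw_dur > 0
            and crop.flw_beg <= g.thermal_time <= crop.flw_beg + crop.flw_dur
        ):
            g.in_flowering = True
            g.beta1_current = gr.flowering_stress(
                g.beta1_current, day.tmax, crop.flw_tmax, crop.flw_dur
            )
        else:
            g.in_flowering = False
    rel_growth = sdw_gain / g.sdw if g.sdw > 0 else 0.0
    g.sdw = min(g.sdw + sdw_gain, g.beta1_current * 1.001 if g.beta1_current else g.sdw + sdw_gain)

    # (7) SOM mineralization and crop N uptake ----------------------------
    soil_mass = min(v_erv, 100.0 * config.mineralization.mpd) * bd * 1000.0
    k2 = ni.k2_mineralization(
        config.texture.clay * 10.0, config.chemistry.caco3, day.tmean
    )
    nsom = ni.nsom_daily(
        soil_mass, config.chemistry.n_org, k2, ni.p_modifier(config.mineralization)
    )
    n.soil_mineral_n += nsom
    n.cum_nsom += nsom
    nupt_target = ni.n_uptake_cum(g.sdw, config.ncurve)
    demand = max(nupt_target - state.cum_nupt_curve, 0.0)
    uptake = min(demand, n.soil_mineral_n)
    n.soil_mineral_n -= uptake
    n.cum_uptake += uptake
    state.cum_nupt_curve = max(state.cum_nupt_curve, nupt_target)

    # (8) leaching on drainage --------------------------------------------
    leached = ni.n_leaching(drainage, w.storage, n, nvz_irrigation=False)
    w.cum_drainage += drainage

    # (9) irrigation decision and application -----------------------------
    phase = _phase(state)
    decision = wa.irrigation_decision(
        w, phase, hyd, config.hardware, g.dat, config.raw_pct,
        root.depth / 100.0, crop.root_h_max / 100.0,
        _establishment_reach(config, root), config.nvz,
    )
    irrigation_net = 0.0
    irr_drain = 0.0
    if decision.irrigate and confirm.irrigation:
        vol_net = confirm.volume_net if confirm.volume_net is not None else decision.volume_net
        vw = vol_net / config.hardware.emitters_per_ha
        bulb = wa.make_bulb(vw, hyd.ks, config.hardware.q_m3_s, hyd.theta_fc)
        state.bulb_dims = (bulb.xf1, bulb.zf1)
        v_erv, v_wrv, v_out = _geometry(state, root)
        w.v_erv, w.v_wrv, w.v_out = v_erv, v_wrv, v_out
        w.taw = fc_wp * v_wrv
        w.raw = config.raw_pct * w.taw
        w.cap_out = fc_wp * v_out
        v_bulb_ha = wa.bulb_volume(bulb.xf1, bulb.zf1) * config.hardware.emitters_per_ha
        wetting = hyd.theta_wp * max(v_bulb_ha - w.v_wetted_max, 0.0)
        w.v_wetted_max = max(w.v_wetted_max, v_bulb_ha)
        fill_erv = min(max(w.taw - w.w_erv, 0.0), max(vol_net - wetting, 0.0))
        fill_out = min(
            max(w.cap_out - w.w_out, 0.0), max(vol_net - wetting - fill_erv, 0.0)
        )
        surplus = max(vol_net - wetting - fill_erv - fill_out, 0.0)
        if config.nvz and surplus > 0:
            # antecedent-moisture credit: recommend less water, no drainage
            vol_net -= surplus
            surplus = 0.0
        w.w_wet += wetting
        w.w_erv += fill_erv
        w.w_out += fill_out
        if surplus > 0:
            leached += ni.n_leaching(surplus, w.storage, n, nvz_irrigation=False)
            w.cum_drainage += surplus
            irr_drain = surplus
        irrigation_net = vol_net
        w.cum_irrigation += vol_net
        decision.volume_net = vol_net
        decision.volume_gross = vol_net * (1.0 + config.hardware.irr_plus / 100.0) / (
            config.hardware.irr_eff / 100.0
        )
        n_in_water = config.irrwt_n * vol_net / 1000.0  # g/m3 * m3/ha -> kg/ha
        n.soil_mineral_n += n_in_water
        n.cum_irrigation_n += n_in_water

    # (10) fertigation dose ------------------------------------------------
    kcp = config.kc
    threshold = (
        config.n_min_res_1 if g.dat <= kcp.t1
        else config.n_min_res_2 if g.dat <= kcp.t3
        else config.n_min_res_3
    )
    horizon = int(min(max(round(w.raw / etc_v) if etc_v > 0 else 10, 1), 10))
    dose = 0.0
    if irrigation_net > 0.0:
        dose = ni.fertigation_decision(
            n, g.dat, threshold,
            forecast_uptake=horizon * demand,
            forecast_nsom=horizon * nsom,
            forecast_interception=horizon * intercepted,
            t1=kcp.t1, t2=kcp.t2, t3=kcp.t3,
            irrigation_event=True, nvz=config.nvz,
        )
        if confirm.n_dose is not None:
            dose = confirm.n_dose
            if config.nvz:
                dose = min(dose, max(n.nvz_budget_remaining, 0.0))
        if dose > 0:
            n.soil_mineral_n += dose
            n.cum_applied += dose
            if config.nvz:
                n.nvz_budget_remaining -= dose

    # (11) maturity check ---------------------------------------------------
    if not in_lag:
        gr.maturity_check(g, crop, gdd_eff, rel_growth)

    record = DailyRecord(
        dat=g.dat, julian_day=day.julian_day, rain=day.rain, tmin=day.tmin,
        tmax=day.tmax, gdd_raw=gdd_raw, k_ts=k_ts, gdd_eff=gdd_eff, sdw=g.sdw,
        thermal_time=g.thermal_time, et0=et0, etc=etc_actual / MM_TO_M3_HA,
        transpiration=transp_v / MM_TO_M3_HA, evaporation=evap_v / MM_TO_M3_HA,
        w_erv=w.w_erv, w_out=w.w_out, taw=w.taw, raw=w.raw,
        depletion=w.depletion, irrigation_net=irrigation_net,
        irrigation_gross=decision.volume_gross if irrigation_net else 0.0,
        duration_h=decision.duration_h if irrigation_net else 0.0,
        n_dose=dose, n_uptake=uptake, nsom=nsom, n_interception=intercepted,
        n_pool=n.soil_mineral_n, drainage=drainage + irr_drain,
        runoff=runoff_mm, leached=leached, qadd=qadd, qrain=qrain,
        redistribution=redis, storage=w.storage,
        phase=phase, water_stress=stressed,
        sdw_check_applied=False, nvz_cap_hit=decision.constrained_by_nvz,
        mature=g.mature,
    )
    state.records.append(record)
    g.dat += 1
    return record


def apply_sdw_check(state: SimulationState, observed_sdw: float) -> None:
    """In-season recalibration from an observed shoot dry weight."""
    if state.growth.mature:
        raise ValueError("cannot apply an SDW check after maturity")
    if not state.records:
        raise ValueError("cannot apply an SDW check before the cycle starts")
    gr.sdw_check(state.growth, observed_sdw, state.config.crop)
    state.records[-1].sdw_check_applied = True


def _run(
    config: SectorConfig,
    series: WeatherSeries,
    max_days: int = 250,
) -> SimulationState:
    state = _init_state(config)
    for day in series:
        if state.growth.mature or state.dat >= max_days:
            break
        step_day(state, day)
    return state


def _schedule_from_state(state: SimulationState) -> FertigationSchedule:
    records = state.records
    rows = [
        {
            "dat": r.dat, "julian_day": r.julian_day,
            "water_m3_ha": round(r.irrigation_gross, 3),
            "duration_h": round(r.duration_h, 3),
            "n_rate_kg_ha": round(r.n_dose, 3),
            "cum_n_kg_ha": 0.0,
            "n_uptake_kg_ha": round(r.n_uptake, 4),
            "nsom_kg_ha": round(r.nsom, 4),
            "n_interception_kg_ha": round(r.n_interception, 4),
            "residual_soil_n_kg_ha": round(r.n_pool, 4),
            "nvz_cap_hit": r.nvz_cap_hit,
        }
        for r in records
        if r.irrigation_net > 0.0
    ]
    events = pd.DataFrame(rows)
    if not events.empty:
        events["cum_n_kg_ha"] = events["n_rate_kg_ha"].cumsum().round(3)
    n = state.nitrogen
    w = state.water
    totals = {
        "irrigation_net_m3_ha": w.cum_irrigation,
        "rain_stored_m3_ha": w.cum_rain_stored,
        "drainage_m3_ha": w.cum_drainage,
        "etc_m3_ha": w.cum_etc,
        "n_applied_kg_ha": n.cum_applied,
        "n_uptake_kg_ha": n.cum_uptake,
        "nsom_kg_ha": n.cum_nsom,
        "n_leached_kg_ha": n.cum_leached,
        "final_sdw_t_ha": state.growth.sdw,
    }
    compliant = None
    if state.config.nvz:
        compliant = n.cum_applied + state.config.n_year <= ni.NVZ_ANNUAL_CAP + 1e-9
    return FertigationSchedule(
        events=events, records=records, season_totals=totals,
        nvz=state.config.nvz, nvz_compliant=compliant,
    )


def run_inseason(config: SectorConfig, series: WeatherSeries) -> FertigationSchedule:
    """Day-to-day season with every recommendation auto-confirmed."""
    return _schedule_from_state(_run(config, series))


def run_preseason(config: SectorConfig, series: WeatherSeries) -> FertigationSchedule:
    """Full-season simulation on a multiannual-mean series.

    In an NVZ the planned fertilizer demand is checked against the
    170 kg/ha/yr ceiling; when it exceeds the budget the attainable
    biomass is recomputed from the N actually available (budget +
    forecast mineralization + initial mineral stock) and the season is
    re-simulated with the recapped asymptote.
    """
    if not series.is_multiannual_mean:
        raise ValueError(
            "the pre-season plan needs a multiannual-mean weather series "
            "(build one with weather.multiannual_mean)"
        )
    if config.nvz:
        probe_cfg = _copy_config(config)
        probe_cfg.nvz = False  # unconstrained probe of the N demand
        probe = _run(probe_cfg, series)
        budget = ni.NVZ_ANNUAL_CAP - config.n_year
        fertilizer_demand = probe.nitrogen.cum_applied
        if fertilizer_demand > budget:
            n_total = (
                budget
                + probe.nitrogen.cum_nsom
                + probe.nitrogen.cum_interception
            )
            sdw_cap = ni.nvz_max_sdw(n_total, config.ncurve)
            if sdw_cap < config.crop.beta1:
                config = _copy_config(config)
                config.crop.beta1 = sdw_cap
                state = _run(config, series)
                sched = _schedule_from_state(state)
                sched.recapped_beta1 = sdw_cap
                return sched
    return _schedule_from_state(_run(config, series))


def _copy_config(config: SectorConfig) -> SectorConfig:
    import copy

    return copy.deepcopy(config)


def write_schedule(schedule: FertigationSchedule, path: str | Path) -> None:
    """Write the event table as CSV; an NVZ run appends a compliance line."""
    path = Path(path)
    with open(path, "w") as fh:
        cols = [
            "dat", "julian_day", "water_m3_ha", "duration_h", "n_rate_kg_ha",
            "cum_n_kg_ha", "n_uptake_kg_ha", "nsom_kg_ha",
            "n_interception_kg_ha", "residual_soil_n_kg_ha", "nvz_cap_hit",
        ]
        df = schedule.events if not schedule.events.empty else pd.DataFrame(columns=cols)
        df.to_csv(fh, index=False)
        if schedule.nvz:
            total = schedule.season_totals["n_applied_kg_ha"]
            fh.write(
                f"# NVZ compliance: applied {total:.2f} kg/ha, "
                f"cap {ni.NVZ_ANNUAL_CAP:.0f} kg/ha/yr, "
                f"compliant={schedule.nvz_compliant}\n"
            )


def read_schedule(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
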