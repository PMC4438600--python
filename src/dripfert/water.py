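"""Daily soil-water balance pieces: crop ET, wet bulbs, runoff, redistribution.

Geometry convention (field frame): the reference plant sits at the origin,
x runs along the row, y across it, z is depth (positive downwards, m).
Emitters are placed from the drip-line/emitter spacing; in a twin-row
layout the drip line lies between the two plant rows (y = 0) and the plant
at y = +row_half_distance.  The effective root volume (ERV) and each wet
bulb are half-truncated ellipsoids hanging from the soil surface; the wet
root volume (WRV) is the sum of the pairwise ERV∩bulb intersections,
integrated on a fixed 1 cm voxel grid.

Internal unit canon: geometry in metres; per-hectare water amounts in
m3/ha (1 mm = 10 m3/ha); Ks is stored in cm/d and converted to m/s only
inside the Schwartzman–Zur bulb-dimension power laws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .soil import SoilHydraulics, hydraulic_conductivity, relative_saturation

__all__ = [
    "KcProfile",
    "WetBulb",
    "WaterState",
    "IrrigationDecision",
    "IrrigationHardware",
    "kc_interpolate",
    "etc_dual",
    "wet_bulb_dimensions",
    "rescale_to_fc",
    "bulb_volume",
    "invert_bulb_volume",
    "wrv_intersection",
    "qirr_available",
    "runoff_cn",
    "effective_rain",
    "redistribution_flux",
    "irrigation_decision",
]

CM_D_TO_M_S = 0.01 / 86400.0
MM_TO_M3_HA = 10.0
VOXEL_M = 0.01  # fixed integration grid step


@dataclass
class KcProfile:
    """FAO-56 crop-coefficient trajectory with optional plastic-mulch modifiers."""

    mode: Literal["single", "dual"] = "dual"
    kc_ini: float = 0.6
    kc_mid: float = 1.15
    kc_end: float = 0.8
    kcb_ini: float = 0.15
    kcb_mid: float = 1.10
    kcb_end: float = 0.7
    ke_ini: float = 0.9
    ke_mid: float = 0.4
    ke_end: float = 0.2
    t1: int = 25
    t2: int = 55
    t3: int = 95
    t4: int = 125
    sc_ini: float = 10.0  # % soil covered
    sc_mid: float = 80.0
    sc_end: float = 70.0
    hp_ini: float = 15.0  # plant height, cm
    hp_mid: float = 60.0
    hp_end: float = 60.0
    mulch: bool = False
    mulch_ke: float = 65.0  # % reduction of Ke under plastic mulch
    mulch_kcb: float = 20.0  # % increase of Kcb under plastic mulch

    def __post_init__(self) -> None:
        if not self.t1 <= self.t2 <= self.t3 <= self.t4:
            raise ValueError("phase days must satisfy t1 <= t2 <= t3 <= t4")
        for name in ("kc", "kcb", "ke"):
            for stage in ("ini", "mid", "end"):
                v = getattr(self, f"{name}_{stage}")
                if not 0.0 <= v <= 1.5:
                    raise ValueError(f"{name}_{stage}={v} outside [0, 1.5]")
        for stage in ("ini", "mid", "end"):
            if not 0.0 <= getattr(self, f"sc_{stage}") <= 100.0:
                raise ValueError("soil-cover percentages must lie in [0, 100]")


def _trapezoid(dat: int, ini: float, mid: float, end: float, p: KcProfile) -> float:
    if dat <= p.t1:
        return ini
    if dat <= p.t2:
        return ini + (mid - ini) * (dat - p.t1) / (p.t2 - p.t1)
    if dat <= p.t3:
        return mid
    return mid + (end - mid) * (dat - p.t3) / (p.t4 - p.t3)


def kc_interpolate(dat: int, profile: KcProfile) -> dict[str, float]:
    """Daily coefficients by the FAO-56 piecewise-linear trajectory.

    Returns ``kc``, ``kcb``, ``ke`` and the interpolated soil-cover
    fraction; mulch multiplies Kcb by (1+Mulch_Kcb/100) and Ke by
    (1-Mulch_Ke/100) (x1.20 and x0.35 at the defaults).
    """
    if dat < 0 or dat > profile.t4:
        raise ValueError(f"dat {dat} outside the crop cycle [0, {profile.t4}]")
    kc = _trapezoid(dat, profile.kc_ini, profile.kc_mid, profile.kc_end, profile)
    kcb = _trapezoid(dat, profile.kcb_ini, profile.kcb_mid, profile.kcb_end, profile)
    ke = _trapezoid(dat, profile.ke_ini, profile.ke_mid, profile.ke_end, profile)
    sc = _trapezoid(dat, profile.sc_ini, profile.sc_mid, profile.sc_end, profile)
    if profile.mulch:
        kcb *= 1.0 + profile.mulch_kcb / 100.0
        ke *= 1.0 - profile.mulch_ke / 100.0
    return {"kc": kc, "kcb": kcb, "ke": ke, "soil_cover_fraction": sc / 100.0}


def etc_dual(
    et0: float,
    kcb: float,
    ke: float,
    covered_fraction: float,
    wet_surface_fraction: float,
    mode: Literal["single", "dual"] = "dual",
    kc: Optional[float] = None,
) -> dict[str, float]:
    """Crop ET (mm) split into transpiration and evaporation.

    Dual mode: T = Kcb*ET0 over the vegetation-covered fraction (taken as
    the ERV top area), E = Ke*ET0 over the wet-bulb surface fraction.
    Single mode: ETc = Kc*ET0 over the covered fraction, no E term.
    """
    for name, f in (("covered_fraction", covered_fraction),
                    ("wet_surface_fraction", wet_surface_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name}={f} outside [0, 1]")
    if mode == "single":
        if kc is None:
            raise ValueError("single-Kc mode needs kc")
        t = kc * et0 * covered_fraction
        return {"etc": t, "transpiration": t, "evaporation": 0.0}
    t = kcb * et0 * covered_fraction
    e = ke * et0 * wet_surface_fraction
    return {"etc": t + e, "transpiration": t, "evaporation": e}


@dataclass(frozen=True)
class WetBulb:
    """Rescaled field-capacity wet bulb under one emitter (metres).

    ``xf1`` is the horizontal semi-axis and ``zf1`` the depth of the
    half-truncated ellipsoid whose volume x theta_FC equals the applied
    water; ``position`` = (x, y) of the emitter in the field frame.
    """

    xf1: float
    zf1: float
    position: tuple[float, float] = (0.0, 0.0)

    @property
    def volume(self) -> float:
        return bulb_volume(self.xf1, self.zf1)

    @property
    def top_area(self) -> float:
        return math.pi * self.xf1**2


def wet_bulb_dimensions(vw: float, ks: float, q: float) -> tuple[float, float]:
    """Schwartzman–Zur bulb size from applied water (per emitter).

    vw: m3 of water applied by one emitter; ks: m/s; q: emitter flow m3/s.
    Returns (Xf, Zf): diameter and depth (m) of the wetted volume,
    Xf = 1.82*Vw^0.22*(Ks/q)^-0.17 and Zf = 2.54*Vw^0.63*(Ks/q)^0.45.
    """
    if q <= 0:
        raise ValueError("emitter flow must be positive")
    if ks <= 0:
        raise ValueError("saturated conductivity must be positive")
    if vw < 0:
        raise ValueError("applied volume must be non-negative")
    if vw == 0:
        return 0.0, 0.0
    ratio = ks / q
    xf = 1.82 * vw**0.22 * ratio**-0.17
    zf = 2.54 * vw**0.63 * ratio**0.45
    return xf, zf


def rescale_to_fc(xf: float, zf: float, vw: float, theta_fc: float) -> tuple[float, float]:
    """Shrink the bulb so the whole wetted volume sits at field capacity.

    Xf1 = (3*Vw*Xf/(2*pi*FC*Zf))^(1/3), Zf1 = Xf1*Zf/Xf.  Xf1 is the
    horizontal semi-axis: with the half-ellipsoid volume
    (2/3)*pi*Xf1^2*Zf1 the identity volume*theta_FC = Vw holds exactly.
    """
    if vw == 0:
        return 0.0, 0.0
    if min(xf, zf, theta_fc) <= 0:
        raise ValueError("xf, zf and theta_fc must be positive")
    xf1 = (3.0 * vw * xf / (2.0 * math.pi * theta_fc * zf)) ** (1.0 / 3.0)
    zf1 = xf1 * zf / xf
    return xf1, zf1


def bulb_volume(xf1: float, zf1: float) -> float:
    """Half-ellipsoid bulb volume (m3), xf1 = horizontal semi-axis."""
    return (2.0 / 3.0) * math.pi * xf1**2 * zf1


def make_bulb(vw: float, ks_cm_d: float, q_m3_s: float, theta_fc: float,
              position: tuple[float, float] = (0.0, 0.0)) -> WetBulb:
    """Applied volume (m3 per emitter) -> field-capacity bulb at a position."""
    xf, zf = wet_bulb_dimensions(vw, ks_cm_d * CM_D_TO_M_S, q_m3_s)
    xf1, zf1 = rescale_to_fc(xf, zf, vw, theta_fc)
    return WetBulb(xf1=xf1, zf1=zf1, position=position)


def invert_bulb_volume(
    target: float,
    dim: Literal["xf1", "zf1"],
    ks_cm_d: float,
    q_m3_s: float,
    theta_fc: float,
    vw_max: float = 10.0,
) -> float:
    """Applied volume (m3/emitter) whose rescaled bulb reaches a target size.

    ``dim`` chooses the controlled dimension (radius for the establishment
    rule, depth for the deepening/full-root rules); both are monotone
    increasing in Vw, solved by bracketed root finding.
    """
    if target <= 0:
        raise ValueError("target dimension must be positive")
    ks = ks_cm_d * CM_D_TO_M_S

    def size(vw: float) -> float:
        xf, zf = wet_bulb_dimensions(vw, ks, q_m3_s)
        xf1, zf1 = rescale_to_fc(xf, zf, vw, theta_fc)
        return xf1 if dim == "xf1" else zf1

    lo, hi = 1e-9, vw_max
    if size(hi) < target:
        raise ValueError(f"target {dim}={target} m unreachable below Vw={vw_max} m3")
    return float(brentq(lambda v: size(v) - target, lo, hi, xtol=1e-10))


def _half_ellipsoid_mask(
    x: np.ndarray, y: np.ndarray, z: np.ndarray,
    cx: float, cy: float, ax: float, ay: float, depth: float,
) -> np.ndarray:
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + (z / depth) ** 2 <= 1.0


def wrv_intersection(
    root_semi_x: float,
    root_semi_y: float,
    root_depth: float,
    root_center: tuple[float, float],
    bulbs: Sequence[WetBulb],
    voxel: float = VOXEL_M,
) -> float:
    """Wet root volume: sum of pairwise ERV∩bulb volumes, m3 per plant.

    Deterministic voxel integration (fixed traversal, voxel <= 1 cm).
    Overlapping bulbs are summed without union correction, matching the
    "sum of the interaction volumes" bookkeeping.
    """
    if min(root_semi_x, root_semi_y, root_depth) <= 0:
        raise ValueError("degenerate root geometry")
    live = [b for b in bulbs if b.xf1 > 0 and b.zf1 > 0]
    if not live:
        return 0.0
    cx, cy = root_center
    half_x = max(root_semi_x, *(abs(b.position[0] - cx) + b.xf1 for b in live))
    half_y = max(root_semi_y, *(abs(b.position[1] - cy) + b.xf1 for b in live))
    depth = max(root_depth, *(b.zf1 for b in live))
    xs = np.arange(cx - half_x + voxel / 2, cx + half_x, voxel)
    ys = np.arange(cy - half_y + voxel / 2, cy + half_y, voxel)
    zs = np.arange(voxel / 2, depth, voxel)
    x = xs[:, None, None]
    y = ys[None, :, None]
    z = zs[None, None, :]
    erv = _half_ellipsoid_mask(x, y, z, cx, cy, root_semi_x, root_semi_y, root_depth)
    vol = 0.0
    for b in live:
        bx, by = b.position
        mask = erv & _half_ellipsoid_mask(x, y, z, bx, by, b.xf1, b.xf1, b.zf1)
        vol += float(mask.sum()) * voxel**3
    return vol


def qirr_available(theta_fc: float, theta_wp: float, wrv: float) -> float:
    """Plant-available water a full wet root volume can hold: (FC-WP)*WRV."""
    return (theta_fc - theta_wp) * wrv


def runoff_cn(p: float, cn: float) -> float:
    """SCS curve-number storm runoff, mm.

    S = (1000/CN - 10)*25.4; Q = (P-0.2S)^2/(P+0.8S) when P > 0.2S else 0.
    """
    if not 0.0 < cn <= 100.0:
        raise ValueError("curve number must be in (0, 100]")
    if p < 0:
        raise ValueError("rainfall must be non-negative")
    s = (1000.0 / cn - 10.0) * 25.4
    if p <= 0.2 * s:
        return 0.0
    return (p - 0.2 * s) ** 2 / (p + 0.8 * s)


def effective_rain(
    p_mm: float,
    runoff_mm: float,
    storage_deficit: float,
) -> dict[str, float]:
    """Partition a storm into stored water and same-day drainage (m3/ha).

    ``storage_deficit`` is the room left below field capacity in the
    tracked soil stores; infiltration beyond it percolates the same day
    and triggers nitrate leaching.
    """
    if runoff_mm > p_mm + 1e-12:
        raise ValueError("runoff cannot exceed rainfall")
    infiltration = (p_mm - runoff_mm) * MM_TO_M3_HA
    stored = min(infiltration, max(storage_deficit, 0.0))
    drainage = infiltration - stored
    return {"qrain": stored, "drainage": drainage,
            "leach_trigger": drainage > 0.0}


def redistribution_flux(
    s1: float,
    s2: float,
    theta_mean: float,
    hyd: SoilHydraulics,
    ve: float,
) -> float:
    """Daily unsaturated flow between two adjacent zones, m3 (bulb->WRV > 0).

    q = (K(theta_mean)/Ks) * (S1-S2) * (theta_s-theta_r) * Ve, i.e. the
    relative conductivity at the mean water content scales the fraction of
    the wetted root-zone volume Ve that can equilibrate per day; the
    transfer is capped so the donor never drops below the receiver.
    """
    for name, s in (("s1", s1), ("s2", s2)):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"{name}={s} outside [0, 1]")
    if ve <= 0 or s1 == s2:
        return 0.0
    k_rel = hydraulic_conductivity(theta_mean, hyd) / hyd.ks
    q = k_rel * (s1 - s2) * (hyd.theta_sat - hyd.theta_res) * ve
    # cap at equalization: moving more than half the saturation gap would
    # overshoot (both zones share the same retention curve and volume scale)
    q_eq = 0.5 * (s1 - s2) * (hyd.theta_sat - hyd.theta_res) * ve
    if q_eq >= 0:
        return float(min(q, q_eq))
    return float(max(q, q_eq))


@dataclass
class IrrigationHardware:
    """Drip-system layout and delivery constants."""

    lines_dist: float = 150.0  # cm between drip lines
    emit_dist: float = 50.0  # cm between emitters on a line
    e_disch: float = 2.0  # L/h per emitter
    irr_eff: float = 90.0  # % system efficiency
    max_irr_dur: float = 6.0  # h
    irr_plus: float = 0.0  # % extra water for uneven distribution

    @property
    def q_m3_s(self) -> float:
        return self.e_disch / 1000.0 / 3600.0

    @property
    def emitters_per_ha(self) -> float:
        return 1e4 / ((self.lines_dist / 100.0) * (self.emit_dist / 100.0))


@dataclass
class WaterState:
    """Lumped per-hectare water stores and the season ledger (m3/ha)."""

    w_erv: float = 0.0  # plant-available water in the ERV (above WP)
    w_out: float = 0.0  # available water in bulbs outside the ERV
    w_wet: float = 0.0  # inert below-WP water bound in wetted soil
    taw: float = 0.0  # (FC-WP)*WRV, refill target and trigger basis
    raw: float = 0.0
    cap_erv: float = 0.0  # (FC-WP)*ERV
    cap_out: float = 0.0
    v_erv: float = 0.0  # m3/ha of effective root volume
    v_wrv: float = 0.0  # m3/ha of ERV∩bulb intersection
    v_out: float = 0.0
    v_wetted_max: float = 0.0  # largest bulb footprint seen, for wetting cost
    cum_irrigation: float = 0.0
    cum_rain_stored: float = 0.0
    cum_runoff: float = 0.0
    cum_drainage: float = 0.0
    cum_etc: float = 0.0
    cum_qadd: float = 0.0
    cum_redistribution: float = 0.0  # bulb -> WRV internal transfers

    @property
    def storage(self) -> float:
        return self.w_erv + self.w_out + self.w_wet

    @property
    def depletion(self) -> float:
        return max(self.taw - min(self.w_erv, self.taw), 0.0)


@dataclass
class IrrigationDecision:
    irrigate: bool
    volume_net: float = 0.0  # m3/ha reaching the soil
    volume_gross: float = 0.0  # m3/ha pumped (IrrPlus and IrrEff applied)
    duration_h: float = 0.0
    phase: Literal["establishment", "root_deepening", "full_root", "ripening"] = "establishment"
    constrained_by_nvz: bool = False
    vw_per_emitter: float = 0.0  # m3, before the NVZ antecedent-moisture credit
    warnings: list[str] = field(default_factory=list)


def irrigation_decision(
    state: WaterState,
    phase: Literal["establishment", "root_deepening", "full_root", "ripening"],
    hydraulics: SoilHydraulics,
    hardware: IrrigationHardware,
    dat: int,
    raw_pct: float,
    root_depth_m: float,
    root_depth_max_m: float,
    establishment_reach_m: float,
    nvz: bool,
) -> IrrigationDecision:
    """Phase-dependent irrigation trigger and volume.

    Day 0 always irrigates.  Afterwards irrigation triggers when the WRV
    depletion reaches RAW = raw_pct*TAW, except in the ripening phase of a
    fruit crop where irrigation stops.  The net volume is the larger of
    the store deficit and the geometric requirement of the phase
    (establishment: rescaled bulb radius covering the neighbouring plants'
    root-zone centers; deepening: bulb depth = current root depth; full
    root: bulb depth = maximum root depth).  In an NVZ the bulb depth is
    capped at the maximum rooting depth by inverting the bulb equations.
    The gross volume adds IrrPlus % and divides by the system efficiency;
    the duration follows from the per-emitter discharge.
    """
    decision = IrrigationDecision(irrigate=False, phase=phase)
    if phase == "ripening":
        return decision
    triggered = dat == 0 or state.depletion >= raw_pct * state.taw > 0.0
    if not triggered:
        return decision

    ks, q = hydraulics.ks, hardware.q_m3_s
    fc = hydraulics.theta_fc
    deficit = (state.taw - min(state.w_erv, state.taw)) + max(
        state.cap_out - state.w_out, 0.0
    )
    vw_deficit = deficit / hardware.emitters_per_ha  # m3/ha -> m3/emitter
    if phase == "establishment":
        try:
            vw_geom = invert_bulb_volume(establishment_reach_m, "xf1", ks, q, fc)
        except ValueError as err:
            decision.warnings.append(str(err))
            vw_geom = 0.0
        target_depth = None
    elif phase == "root_deepening":
        vw_geom = invert_bulb_volume(root_depth_m, "zf1", ks, q, fc)
        target_depth = root_depth_m
    else:  # full_root
        vw_geom = invert_bulb_volume(root_depth_max_m, "zf1", ks, q, fc)
        target_depth = root_depth_max_m
    vw = max(vw_geom, vw_deficit)
    if nvz:
        vw_cap = invert_bulb_volume(root_depth_max_m, "zf1", ks, q, fc)
        if vw > vw_cap + 1e-12:
            if phase == "establishment" and vw_geom > vw_cap:
                decision.warnings.append(
                    "NVZ depth cap prevents the establishment-phase bulb radius "
                    f"target of {establishment_reach_m:.2f} m"
                )
            vw = vw_cap
            decision.constrained_by_nvz = True
    volume_net = vw * hardware.emitters_per_ha  # m3/ha
    volume_gross = volume_net * (1.0 + hardware.irr_plus / 100.0) / (
        hardware.irr_eff / 100.0
    )
    duration = volume_gross / hardware.emitters_per_ha / (hardware.e_disch / 1000.0)
    if duration > hardware.max_irr_dur:
        decision.warnings.append(
            f"required duration {duration:.2f} h exceeds MaxIrrDur "
            f"{hardware.max_irr_dur} h; volume capped"
        )
        duration = hardware.max_irr_dur
        volume_gross = duration * (hardware.e_disch / 1000.0) * hardware.emitters_per_ha
        volume_net = volume_gross * (hardware.irr_eff / 100.0) / (
            1.0 + hardware.irr_plus / 100.0
        )
        vw = volume_net / hardware.emitters_per_ha
    decision.irrigate = True
    decision.vw_per_emitter = vw
    decision.volume_net = volume_net
    decision.volume_gross = volume_gross
    decision.duration_h = duration
    return decision
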