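"""Thermal-time logistic shoot growth with stress corrections and root geometry.

Shoot dry weight (SDW, t/ha) follows a logistic curve in accumulated
growing degree days, SDW = beta1/(1+exp(beta2+beta3*t)).  Daily thermal
time is reduced linearly between the onset (T_M1) and cut-off (T_M2)
temperatures; hot days during flowering of fruit crops permanently lower
the asymptote beta1; water shortage reduces the day's SDW gain through a
biomass response factor.  A mid-season observed-SDW check ("SDW check")
rescales T_M2 and beta1 from the observed/predicted ratio.  The effective
root volume is a half-truncated ellipsoid growing linearly from initial to
maximum dimensions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

__all__ = [
    "CropGrowthParams",
    "GrowthState",
    "RootGeometry",
    "gdd",
    "thermal_stress_coeff",
    "logistic_sdw",
    "logistic_inverse",
    "beta1_from_yield",
    "flowering_stress",
    "water_stress_sdw",
    "sdw_check",
    "align_cycle_to_plantlet",
    "advance_roots",
    "maturity_check",
]

PLATEAU_REL_GROWTH = 0.004  # daily relative SDW increase marking the ripening plateau

HarvestType = Literal["ripe_fruit", "immature", "vegetative"]


@dataclass
class CropGrowthParams:
    """Crop calibration constants for growth, stress response and roots."""

    beta1: float  # t/ha, logistic asymptote
    beta2: float
    beta3: float  # < 0 for growth in thermal time
    t_base: float  # deg C
    t_m1: float  # onset of thermal stress, deg C
    t_m2: float  # growth cut-off, deg C
    flw_beg: float = 0.0  # flowering start, deg C d
    flw_dur: float = 0.0  # flowering duration, deg C d
    flw_tmax: float = 99.0  # deg C
    ky_b: float = 1.0  # biomass response factor to water stress
    k_t1: float = 0.0
    k_t2: float = 0.0
    k_t3: float = 0.0
    k_sdw1: float = 1.0
    k_sdw2: float = 1.0
    plts_ref: float = 1.0  # reference plantlet mass, g
    plts_gr: float = 0.1  # lag-phase growth rate, g/day
    ts_min: float = 0.0  # deg C d
    ts_max: float = 1e9  # deg C d
    d_sdwstop: int = 5  # consecutive plateau days for fruit-crop maturity
    hrvst_type: HarvestType = "ripe_fruit"
    exp_yld: float = 0.0  # g/plant fresh
    yld_dw: float = 0.0  # % DW in fresh yield
    hi: float = 1.0
    nplant: float = 30000.0  # plants/ha
    root_r_ini: float = 5.0  # cm
    root_r_max: float = 40.0  # cm
    root_h_ini: float = 10.0  # cm
    root_h_max: float = 45.0  # cm
    root_d_max: int = 50  # days to reach maxima
    twin_row_r1_reduction: float = 0.25  # fraction, applied in sandy twin-row layouts

    def __post_init__(self) -> None:
        if not self.t_base < self.t_m1 < self.t_m2:
            raise ValueError("need t_base < t_m1 < t_m2")
        if not 0 < self.hi <= 1:
            raise ValueError("harvest index must be in (0, 1]")
        if self.ts_min > self.ts_max:
            raise ValueError("ts_min must not exceed ts_max")
        if self.beta1 <= 0:
            raise ValueError("beta1 must be positive")


@dataclass
class GrowthState:
    """Mutable crop state carried across days."""

    thermal_time: float = 0.0
    sdw: float = 0.0  # t/ha
    beta1_current: float = 0.0
    t_m2_current: float = 0.0
    days_low_growth: int = 0
    in_flowering: bool = False
    mature: bool = False
    dat: int = 0
    lag_days_left: int = 0
    plantlet_mass: float = 0.0  # g, during the lag phase


@dataclass(frozen=True)
class RootGeometry:
    """Half-truncated-ellipsoid effective root volume (cm units)."""

    r: float  # radius along the row, cm
    r1: float  # orthogonal radius, cm (reduced for twin rows on sand)
    depth: float  # cm
    center_offset: float = 0.0  # shift toward the emitter, cm (= r1 reduction)

    def __post_init__(self) -> None:
        if min(self.r, self.r1, self.depth) <= 0:
            raise ValueError("root radii and depth must be positive")
        if self.r1 > self.r + 1e-9:
            raise ValueError("r1 must not exceed r")

    @property
    def erv(self) -> float:
        """Effective root volume, cm3: pi*r*r1*(2*depth/3)."""
        return math.pi * self.r * self.r1 * (2.0 * self.depth / 3.0)


def gdd(tmax: float, tmin: float, t_base: float) -> float:
    """Daily growing degree days: max(0, (Tmax+Tmin)/2 - Tbase)."""
    if tmin > tmax:
        raise ValueError("tmin > tmax")
    return max(0.0, 0.5 * (tmax + tmin) - t_base)


def thermal_stress_coeff(tmax: float, t_m1: float, t_m2: float) -> float:
    """Heat-stress multiplier on the day's GDD: 1 below T_M1, 0 above T_M2."""
    if t_m1 >= t_m2:
        raise ValueError("t_m1 must be below t_m2")
    if tmax <= t_m1:
        return 1.0
    if tmax >= t_m2:
        return 0.0
    return 1.0 - (tmax - t_m1) / (t_m2 - t_m1)


def logistic_sdw(thermal_time: float, beta1: float, beta2: float, beta3: float) -> float:
    """SDW (t/ha) on the logistic curve at the given thermal time."""
    x = beta2 + beta3 * thermal_time
    if x > 700.0:  # exp overflow guard; curve is flat-zero out here
        return 0.0
    return beta1 / (1.0 + math.exp(x))


def logistic_inverse(sdw: float, beta1: float, beta2: float, beta3: float) -> float:
    """Thermal time at which the curve reaches ``sdw`` (0 < sdw < beta1)."""
    if not 0.0 < sdw < beta1:
        raise ValueError(f"sdw must be in (0, beta1={beta1}), got {sdw}")
    return (math.log(beta1 / sdw - 1.0) - beta2) / beta3


def beta1_from_yield(exp_yld: float, yld_dw: float, hi: float, nplant: float) -> float:
    """Logistic asymptote (t/ha) from expected fresh yield.

    beta1 = Exp_yld * YldDW/100 / HI * nplant, converted g/ha -> t/ha.
    """
    if hi <= 0:
        raise ValueError("harvest index must be positive")
    return exp_yld * yld_dw / 100.0 / hi * nplant / 1e6


def flowering_stress(
    beta1_current: float, tmax: float, flw_tmax: float, flw_dur: float
) -> float:
    """Permanent asymptote reduction on a hot flowering day.

    new_beta1 = beta1*(1-(Tmax-Flw_Tmax)/Flw_dur), applied only when
    Tmax exceeds Flw_Tmax; repeated hot days compound on the running
    value.  A non-positive result is floored at zero (crop failure).
    """
    if tmax <= flw_tmax:
        return beta1_current
    if flw_dur <= 0:
        raise ValueError("flw_dur must be positive")
    new_beta1 = beta1_current * (1.0 - (tmax - flw_tmax) / flw_dur)
    if new_beta1 <= 0.0:
        warnings.warn("flowering heat stress drove beta1 to zero (crop failure)")
        return 0.0
    return new_beta1


def water_stress_sdw(
    sdw_m_daily: float,
    etc: float,
    raw_available: float,
    taw: float,
    raw: float,
    ky_b: float,
    literal_eq7: bool = False,
) -> float:
    """Reduce the day's potential SDW gain under water shortage.

    Stress applies only when the remaining readily available water cannot
    cover the day's crop ET.  ``etc_l`` is the part of ETc drawn beyond
    the readily available water, clamped to the stress buffer TAW-RAW.
    Default (monotone) reading: loss fraction = ky_b*etc_l/(TAW-RAW), so
    the loss grows as the soil dries toward wilting point.  The printed
    compatibility form (``literal_eq7``) uses
    1 - SDWa/SDWm = ky_b*(1 - etc_l/(TAW-RAW)) instead.
    """
    if raw_available >= etc:
        return sdw_m_daily
    if taw <= raw:
        raise ValueError("need taw > raw")
    etc_l = min(max(etc - max(raw_available, 0.0), 0.0), taw - raw)
    if literal_eq7:
        loss = ky_b * (1.0 - etc_l / (taw - raw))
    else:
        loss = ky_b * etc_l / (taw - raw)
    return max(sdw_m_daily * (1.0 - loss), 0.0)


def sdw_check(
    state: GrowthState,
    sdw_observed: float,
    params: CropGrowthParams,
    sdw_predicted: Optional[float] = None,
) -> tuple[float, float]:
    """Mid-season recalibration from an observed SDW measurement.

    With rho = observed/predicted:
    new T_M2 = K_T1*rho^2 + K_T2*rho + K_T3 (when any K_T is set), and
    new beta1 = beta1 * K_SDW1 * rho^K_SDW2.  Both replace the running
    values; the curve is rescaled, not refit, and subsequent gains are
    evaluated incrementally so state.sdw stays continuous.
    Returns the updated (t_m2_current, beta1_current) and mutates state.
    """
    pred = sdw_predicted if sdw_predicted is not None else state.sdw
    if pred <= 0:
        raise ValueError("predicted SDW must be positive on the check day")
    if sdw_observed <= 0:
        raise ValueError("observed SDW must be positive")
    rho = sdw_observed / pred
    if params.k_t1 or params.k_t2 or params.k_t3:
        state.t_m2_current = params.k_t1 * rho**2 + params.k_t2 * rho + params.k_t3
    state.beta1_current = state.beta1_current * params.k_sdw1 * rho**params.k_sdw2
    return state.t_m2_current, state.beta1_current


def align_cycle_to_plantlet(
    plts_dw: float, params: CropGrowthParams
) -> tuple[int, float]:
    """Initial lag/offset from the transplant plantlet mass.

    Lighter plantlets than the calibration reference are held in a lag
    phase growing at ``plts_gr`` g/day until they reach ``plts_ref``;
    heavier ones shift the curve forward by starting at the thermal time
    where the logistic matches the observed per-hectare SDW.
    Returns (lag_days, initial_thermal_time).
    """
    if plts_dw <= 0:
        raise ValueError("plantlet mass must be positive")
    if plts_dw > 100.0 * params.plts_ref:
        raise ValueError("plantlet mass implausibly large (>100x reference)")
    if plts_dw < params.plts_ref:
        lag = math.ceil((params.plts_ref - plts_dw) / params.plts_gr - 1e-9)
        return lag, 0.0
    if plts_dw == params.plts_ref:
        return 0, 0.0
    sdw0 = plts_dw * params.nplant / 1e6  # g/plant -> t/ha
    tt0 = logistic_inverse(min(sdw0, 0.999 * params.beta1),
                           params.beta1, params.beta2, params.beta3)
    return 0, max(tt0, 0.0)


def advance_roots(
    dat: int,
    params: CropGrowthParams,
    twin_row_sandy: bool = False,
) -> RootGeometry:
    """Root geometry on day ``dat``: linear growth to the maxima, then constant.

    In a twin-row layout on sandy soil the orthogonal radius r1 is reduced
    (default 25 %) and the ellipsoid center shifts toward the emitter by
    the same amount.
    """
    if dat < 0:
        raise ValueError("dat must be >= 0")
    f = min(dat / params.root_d_max, 1.0) if params.root_d_max > 0 else 1.0
    r = params.root_r_ini + f * (params.root_r_max - params.root_r_ini)
    depth = params.root_h_ini + f * (params.root_h_max - params.root_h_ini)
    r1 = r
    offset = 0.0
    if twin_row_sandy:
        reduction = params.twin_row_r1_reduction * r
        r1 = r - reduction
        offset = reduction
    return RootGeometry(r=r, r1=r1, depth=depth, center_offset=offset)


def maturity_check(
    state: GrowthState,
    params: CropGrowthParams,
    gdd_today: float,
    rel_growth_today: float,
) -> bool:
    """Update the plateau counter and decide crop maturity.

    Non-fruit crops mature at ts_min.  Fruit crops need d_sdwstop
    consecutive positive-GDD days with relative SDW growth below 0.4 %
    (counter resets on any other day) plus ts_min; ts_max forces maturity
    regardless.
    """
    if state.thermal_time >= params.ts_max:
        state.mature = True
        return True
    if params.hrvst_type != "ripe_fruit":
        state.mature = state.thermal_time >= params.ts_min
        return state.mature
    if gdd_today > 0.0 and rel_growth_today < PLATEAU_REL_GROWTH:
        state.days_low_growth += 1
    else:
        state.days_low_growth = 0
    state.mature = (
        state.days_low_growth >= params.d_sdwstop
        and state.thermal_time >= params.ts_min
    )
    return state.mature
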