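"""Daily nitrogen budget: critical-curve demand, mineralization, interception,
leaching, the fertigation dose rule and the nitrate-vulnerable-zone cap.

Crop N demand follows the critical dilution curve %N = a*SDW^-b, whose
integral form Nupt = 10*a*SDW^(1-b) (kg/ha) gives cumulative uptake as a
function of shoot dry weight.  Soil organic matter mineralizes at a
Hénin–Dupuis-type coefficient k2 driven by clay, carbonate and mean air
temperature, modulated by a management product P = fr*I*Ts.  Root growth
intercepts the pre-season mineral N stock in the newly explored soil.  In
an NVZ the season's fertilizer inputs are capped at 170 kg/ha/yr and the
feasible maximum biomass is recomputed by inverting the uptake curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

__all__ = [
    "NCurveParams",
    "MineralizationParams",
    "NState",
    "NVZ_ANNUAL_CAP",
    "critical_n_pct",
    "n_uptake_cum",
    "k2_mineralization",
    "p_modifier",
    "nsom_daily",
    "n_interception",
    "fertigation_decision",
    "n_leaching",
    "nvz_max_sdw",
]

NVZ_ANNUAL_CAP = 170.0  # kg N/ha/yr, EU Nitrates Directive ceiling

FR_TABLE_VALUES = {0.8, 0.9, 1.0, 1.1, 1.2, 1.3}
TS_VALUES = {1.0, 0.8, 0.5}


@dataclass(frozen=True)
class NCurveParams:
    """Critical N dilution curve: a = %N at SDW = 1 t/ha, b = dilution slope."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be positive")
        if not 0.0 < self.b < 1.0:
            raise ValueError("b must be in (0, 1)")


@dataclass(frozen=True)
class MineralizationParams:
    """Management modifiers of the mineralization coefficient."""

    fr: float = 1.0  # crop-residue / organic-input coefficient (tabled grid)
    i_factor: float = 1.25  # mineralization weight factor
    ts_factor: float = 1.0  # tillage factor: 1.0 / 0.8 / 0.5
    mpd: float = 40.0  # maximum plough depth, cm

    def __post_init__(self) -> None:
        if not any(math.isclose(self.fr, v) for v in FR_TABLE_VALUES):
            raise ValueError(f"fr={self.fr} outside the tabled grid {sorted(FR_TABLE_VALUES)}")
        if not any(math.isclose(self.ts_factor, v) for v in TS_VALUES):
            raise ValueError(f"ts_factor must be one of {sorted(TS_VALUES)}")


@dataclass
class NState:
    """Mineral N pool in the effective root volume plus the season ledger (kg/ha)."""

    soil_mineral_n: float = 0.0
    cum_uptake: float = 0.0
    cum_nsom: float = 0.0
    cum_interception: float = 0.0
    cum_applied: float = 0.0
    cum_irrigation_n: float = 0.0
    cum_leached: float = 0.0
    nvz_budget_remaining: float = math.inf


def critical_n_pct(sdw: float, params: NCurveParams) -> float:
    """Critical shoot N concentration (%): a*SDW^-b, plateaued at a below 1 t/ha.

    The power law diverges as SDW -> 0, so below 1 t/ha the concentration
    is held constant at ``a`` (standard critical-curve convention).
    """
    if sdw <= 0:
        raise ValueError("sdw must be positive")
    if sdw <= 1.0:
        return params.a
    return params.a * sdw ** (-params.b)


def n_uptake_cum(sdw: float, params: NCurveParams) -> float:
    """Cumulative crop N uptake (kg/ha): 10*a*SDW^(1-b)."""
    if sdw < 0:
        raise ValueError("sdw must be non-negative")
    if sdw == 0.0:
        return 0.0
    return 10.0 * params.a * sdw ** (1.0 - params.b)


def k2_mineralization(
    clay: float, caco3: float, tmean: float, literal_grouping: bool = False
) -> float:
    """Annual mineralization coefficient from texture, carbonate and temperature.

    Adopted grouping: k2 = [1200/((clay+200)*(0.3*CaCO3+200))] * max(0, T/2-5),
    zero at Tmean <= 10 C.  ``literal_grouping`` divides by the temperature
    term as well (the printed chain of factors read as one denominator).
    Clay and CaCO3 in g/kg, Tmean in C.
    """
    if clay < 0 or caco3 < 0:
        raise ValueError("clay and caco3 must be non-negative")
    base = 1200.0 / ((clay + 200.0) * (0.3 * caco3 + 200.0))
    temp = tmean / 2.0 - 5.0
    if temp <= 0.0:
        return 0.0
    if literal_grouping:
        return base / temp
    return base * temp


def p_modifier(params: MineralizationParams) -> float:
    """Mineralization modifier P = fr * I * Ts."""
    return params.fr * params.i_factor * params.ts_factor


def nsom_daily(soil_wt: float, n_org: float, k2: float, p: float) -> float:
    """Daily N released by SOM mineralization (kg/ha/day).

    NSOM = (Soil_wt * Norg/1000 * k2 * P)/365 with Soil_wt the soil mass
    (kg/ha) holding most of the roots (ERV mass capped at plough depth)
    and Norg in g/kg.
    """
    if min(soil_wt, n_org, k2, p) < 0:
        raise ValueError("all inputs must be non-negative")
    return soil_wt * n_org / 1000.0 * k2 * p / 365.0


def n_interception(
    delta_erv_m3_ha: float,
    soil_no3: float,
    soil_nh4: float,
    bulk_density: float,
) -> float:
    """Mineral-N stock intercepted by the day's root growth (kg/ha).

    The pre-season NO3-N + NH4-N concentration (mg/kg) times the mass of
    soil newly explored by the roots that day (delta ERV, m3/ha, times
    bulk density).  Zero once the roots are at their maxima.
    """
    if delta_erv_m3_ha < 0:
        raise ValueError("delta_erv must be non-negative")
    soil_mass_kg_ha = delta_erv_m3_ha * bulk_density * 1000.0  # g/cm3 -> kg/m3
    return (soil_no3 + soil_nh4) * soil_mass_kg_ha * 1e-6


def fertigation_decision(
    nstate: NState,
    dat: int,
    threshold: float,
    forecast_uptake: float,
    forecast_nsom: float,
    forecast_interception: float,
    t1: int,
    t2: int,
    t3: int,
    irrigation_event: bool,
    nvz: bool,
) -> float:
    """N dose (kg/ha) to dissolve in a triggered irrigation.

    Application triggers when the mineral pool is below the stage
    threshold; the dose is the forecast crop uptake until the next
    presumable irrigation net of the simultaneous mineralization and
    interception, scaled by the stage coefficient K_Nrate (1.2 up to T1,
    2.5 to T2, 0.7 in the first 60 % of the mid phase, 0.3 in the rest,
    0 after T3).  Fertilizer travels with irrigation water, so a dose
    without an event is an error; NVZ caps at the remaining budget.
    """
    if dat > t3:
        return 0.0
    if nstate.soil_mineral_n >= threshold:
        return 0.0
    if dat <= t1:
        k_nrate = 1.2
    elif dat <= t2:
        k_nrate = 2.5
    elif dat <= t2 + 0.6 * (t3 - t2):
        k_nrate = 0.7
    else:
        k_nrate = 0.3
    dose = max(forecast_uptake - forecast_nsom - forecast_interception, 0.0) * k_nrate
    if dose <= 0.0:
        return 0.0
    if not irrigation_event:
        raise ValueError("an N dose needs an irrigation event to carry it")
    if nvz:
        dose = min(dose, max(nstate.nvz_budget_remaining, 0.0))
    return dose


def n_leaching(
    drainage_m3_ha: float,
    stored_water_m3_ha: float,
    nstate: NState,
    nvz_irrigation: bool = False,
) -> float:
    """N washed out with drainage (kg/ha), removed from the pool.

    The dissolved pool leaches in proportion to the drained fraction of
    the water stored in the root zone at the moment of drainage.  NVZ-
    managed irrigation produces no drainage, hence no leaching (only rain
    can leach in an NVZ).
    """
    if drainage_m3_ha <= 0.0 or nvz_irrigation:
        return 0.0
    total = stored_water_m3_ha + drainage_m3_ha
    if total <= 0.0:
        return 0.0
    frac = min(drainage_m3_ha / total, 1.0)
    leached = nstate.soil_mineral_n * frac
    nstate.soil_mineral_n -= leached
    nstate.cum_leached += leached
    return leached


def nvz_max_sdw(n_available_total: float, params: NCurveParams) -> float:
    """Maximum biomass (t/ha) the capped N supply can sustain.

    Inverts the uptake curve: SDW_nvz = (N_total/(10a))^(1/(1-b)).
    """
    if n_available_total < 0:
        raise ValueError("available N must be non-negative")
    if n_available_total == 0.0:
        return 0.0
    return (n_available_total / (10.0 * params.a)) ** (1.0 / (1.0 - params.b))
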