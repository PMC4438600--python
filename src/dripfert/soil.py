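"""Soil texture, pedotransfer functions and van Genuchten–Mualem hydraulics.

The water-balance engine treats the soil as a single homogeneous layer
described by its USDA textural class, the water contents at field capacity
(``theta_fc``) and permanent wilting point (``theta_wp``), and the van
Genuchten retention / Mualem conductivity parameters used by the
redistribution step.  Where laboratory values are missing, ``pedotransfer``
estimates ``theta_fc``/``theta_wp`` from texture by one of nine published
regressions (the Saxton form, method 9, is the default) and class-mean
defaults from Carsel & Parrish (1988) fill in Ks, theta_r, theta_s, alpha
and n.
"""

from __future__ import annotations

import math
from typing import Optional

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "SoilTexture",
    "SoilHydraulics",
    "SoilChemistry",
    "USDA_CLASSES",
    "CARSEL_PARRISH",
    "classify_usda",
    "pedotransfer",
    "default_ks",
    "default_hydraulics",
    "relative_saturation",
    "pressure_head",
    "hydraulic_conductivity",
]

TEXTURE_SUM_TOL = 0.5  # percent points; lab reports rarely sum exactly to 100


class SoilTexture(BaseModel):
    """Mineral-soil particle-size distribution in mass percent.

    ``organic_matter`` is percent OM (a sector config storing SOM in g/kg
    converts via %OM = SOM/10 at the boundary).  ``bulk_density`` in g/cm3
    is optional; method 9 can estimate it.
    """

    sand: float = Field(ge=0, le=100)
    silt: float = Field(ge=0, le=100)
    clay: float = Field(ge=0, le=100)
    organic_matter: Optional[float] = Field(default=None, ge=0, le=100)
    bulk_density: Optional[float] = Field(default=None, gt=0.5, lt=2.2)

    @model_validator(mode="after")
    def _check_sum(self) -> "SoilTexture":
        total = self.sand + self.silt + self.clay
        if abs(total - 100.0) > TEXTURE_SUM_TOL:
            raise ValueError(
                f"sand+silt+clay = {total:.2f}, must equal 100 ± {TEXTURE_SUM_TOL}"
            )
        if abs(total - 100.0) > 1e-12:  # renormalize small lab drift
            f = 100.0 / total
            object.__setattr__(self, "sand", self.sand * f)
            object.__setattr__(self, "silt", self.silt * f)
            object.__setattr__(self, "clay", self.clay * f)
        return self


class SoilHydraulics(BaseModel):
    """Retention and conductivity constants of the (single) soil layer."""

    theta_fc: float = Field(gt=0, lt=1)
    theta_wp: float = Field(gt=0, lt=1)
    theta_sat: float = Field(gt=0, le=1)
    theta_res: float = Field(ge=0, lt=1)
    ks: float = Field(gt=0, description="saturated conductivity, cm/d")
    vg_alpha: float = Field(gt=0, description="van Genuchten alpha, 1/cm")
    vg_n: float = Field(gt=1)
    usda_class: str = ""
    bulk_density: Optional[float] = None

    @model_validator(mode="after")
    def _check_order(self) -> "SoilHydraulics":
        if not (self.theta_res < self.theta_wp < self.theta_fc < self.theta_sat):
            raise ValueError(
                "need theta_res < theta_wp < theta_fc < theta_sat, got "
                f"{self.theta_res}, {self.theta_wp}, {self.theta_fc}, {self.theta_sat}"
            )
        return self

    @property
    def vg_m(self) -> float:
        return 1.0 - 1.0 / self.vg_n


class SoilChemistry(BaseModel):
    """Chemical analysis at the start of the cycle (all non-negative)."""

    som: float = Field(ge=0, description="soil organic matter, g/kg")
    n_org: float = Field(ge=0, description="organic N, g/kg")
    no3_n: float = Field(ge=0, description="nitrate-N, mg/kg")
    nh4_n: float = Field(ge=0, description="ammonium-N, mg/kg")
    caco3: float = Field(ge=0, description="total carbonate, g/kg")


USDA_CLASSES = (
    "sand",
    "loamy sand",
    "sandy loam",
    "loam",
    "silt loam",
    "silt",
    "sandy clay loam",
    "clay loam",
    "silty clay loam",
    "sandy clay",
    "silty clay",
    "clay",
)

# Carsel & Parrish (1988) class means: theta_r, theta_s, alpha (1/cm), n,
# Ks (cm/d, converted from the published cm/h values).
CARSEL_PARRISH: dict[str, dict[str, float]] = {
    "sand": dict(theta_res=0.045, theta_sat=0.43, vg_alpha=0.145, vg_n=2.68, ks=712.8),
    "loamy sand": dict(theta_res=0.057, theta_sat=0.41, vg_alpha=0.124, vg_n=2.28, ks=350.2),
    "sandy loam": dict(theta_res=0.065, theta_sat=0.41, vg_alpha=0.075, vg_n=1.89, ks=106.1),
    "loam": dict(theta_res=0.078, theta_sat=0.43, vg_alpha=0.036, vg_n=1.56, ks=24.96),
    "silt": dict(theta_res=0.034, theta_sat=0.46, vg_alpha=0.016, vg_n=1.37, ks=6.00),
    "silt loam": dict(theta_res=0.067, theta_sat=0.45, vg_alpha=0.020, vg_n=1.41, ks=10.80),
    "sandy clay loam": dict(theta_res=0.100, theta_sat=0.39, vg_alpha=0.059, vg_n=1.48, ks=31.44),
    "clay loam": dict(theta_res=0.095, theta_sat=0.41, vg_alpha=0.019, vg_n=1.31, ks=6.24),
    "silty clay loam": dict(theta_res=0.089, theta_sat=0.43, vg_alpha=0.010, vg_n=1.23, ks=1.68),
    "sandy clay": dict(theta_res=0.100, theta_sat=0.38, vg_alpha=0.027, vg_n=1.23, ks=2.88),
    "silty clay": dict(theta_res=0.070, theta_sat=0.36, vg_alpha=0.005, vg_n=1.09, ks=0.48),
    "clay": dict(theta_res=0.068, theta_sat=0.38, vg_alpha=0.008, vg_n=1.09, ks=4.80),
}


def classify_usda(texture: SoilTexture) -> str:
    """Return the USDA textural class of a texture (standard triangle rules)."""
    sa, si, cl = texture.sand, texture.silt, texture.clay
    if si + 1.5 * cl < 15:
        return "sand"
    if si + 1.5 * cl >= 15 and si + 2 * cl < 30:
        return "loamy sand"
    if (7 <= cl < 20 and sa > 52 and si + 2 * cl >= 30) or (
        cl < 7 and si < 50 and si + 2 * cl >= 30
    ):
        return "sandy loam"
    if 7 <= cl < 27 and 28 <= si < 50 and sa <= 52:
        return "loam"
    if (si >= 50 and 12 <= cl < 27) or (50 <= si < 80 and cl < 12):
        return "silt loam"
    if si >= 80 and cl < 12:
        return "silt"
    if 20 <= cl < 35 and si < 28 and sa > 45:
        return "sandy clay loam"
    if 27 <= cl < 40 and 20 < sa <= 45:
        return "clay loam"
    if 27 <= cl < 40 and sa <= 20:
        return "silty clay loam"
    if cl >= 35 and sa > 45:
        return "sandy clay"
    if cl >= 40 and si >= 40:
        return "silty clay"
    if cl >= 40 and sa <= 45 and si < 40:
        return "clay"
    raise ValueError(f"texture outside USDA triangle: sand={sa}, silt={si}, clay={cl}")


def _need(value: Optional[float], name: str, method: int) -> float:
    if value is None:
        raise ValueError(f"pedotransfer method {method} requires {name}")
    return value


def pedotransfer(texture: SoilTexture, method: int = 9) -> dict[str, float]:
    """Estimate field capacity and wilting point from texture.

    Nine published regressions (methods 1..9); method 9 (Saxton) is the
    default and additionally returns saturated content and bulk density
    BD = (1 - sat)*2.65.  Returns a dict with keys ``theta_fc``,
    ``theta_wp`` and, for method 9, ``theta_sat`` and ``bulk_density``.
    """
    sa, si, cl = texture.sand, texture.silt, texture.clay
    om, bd = texture.organic_matter, texture.bulk_density
    if method == 1:
        om = _need(om, "organic_matter", 1)
        bd = _need(bd, "bulk_density", 1)
        fc = 0.3486 - 1.8e-3 * sa + 3.9e-3 * cl + 0.0228 * om - 0.0738 * bd
        wp = 0.0854 - 4e-4 * sa + 4.4e-3 * cl + 0.0122 * om - 0.0182 * bd
    elif method == 2:
        cs = cl + si
        fc = math.exp(-3.43 + 0.419 * cs**0.5 - 1.83e-3 * cs**1.5)
        wp = math.exp(-4.384 + 0.404 * cs**0.5 - 9.85e-7 * cs**3)
    elif method == 3:
        bd = _need(bd, "bulk_density", 3)
        if sa >= 75:
            fc = 0.73426 - 1.45e-3 * sa - 0.29176 * bd
        else:
            fc = 0.5784 + 2.27e-3 * cl - 0.28438 * bd
        wp = 0.02413 + 3.73e-3 * cl
    elif method == 4:
        om = _need(om, "organic_matter", 4)
        bd = _need(bd, "bulk_density", 4)
        fc = 0.2668 + 3.9e-3 * cl + 1.3e-3 * si + 4.6e-3 * om - 0.0764 * bd
        wp = 0.0611 + 4e-3 * cl + 5e-4 * si + 5e-3 * om
    elif method == 5:
        fc = 1e-2 * (11.83 + 0.96 * cl - 0.008 * cl**2)
        wp = 1e-2 * (1.74 + 0.76 * cl - 0.005 * cl**2)
    elif method == 6:
        fc = (0.043 + 0.004 * cl) / (0.471 + 0.00411 * cl)
        wp = (0.008 + 3.67e-3 * cl) / (0.471 + 0.00411 * cl)
    elif method == 7:
        bd = _need(bd, "bulk_density", 7)
        fc = 1e-2 * bd * (
            2.65 + 1.105 * cl - 0.01896 * cl**2 + 1.678e-4 * cl**3
            + 15.12 * bd - 6.745 * bd**2 - 0.1975 * cl * bd
        )
        wp = 1e-2 * bd * (0.2805 * cl + 9.615e-4 * cl**2)
    elif method == 8:
        bd = _need(bd, "bulk_density", 8)
        fc = 1e-2 * (20.81 + 0.45 * cl + 0.13 * si - 5.95 * bd)
        wp = 1e-2 * (1.48 + 0.84 * cl - 0.0055 * cl**2)
    elif method == 9:
        a = math.exp(-4.396 - 0.0715 * cl - 4.88e-4 * sa**2 - 4.285e-5 * sa**2 * cl)
        b = -3.14 - 2.22e-3 * cl**2 - 3.484e-5 * sa**2 * cl
        # clay = 0 would make log10 diverge; the regression was fit on cl >= 5
        sat = 0.332 - 7.251e-4 * sa + 0.1276 * math.log10(max(cl, 1e-6))
        wp = (15.0 / a) ** (1.0 / b)
        fc = (0.333 / a) ** (1.0 / b)
        return {
            "theta_fc": fc,
            "theta_wp": wp,
            "theta_sat": sat,
            "bulk_density": (1.0 - sat) * 2.65,
        }
    else:
        raise ValueError(f"pedotransfer method must be 1..9, got {method}")
    return {"theta_fc": fc, "theta_wp": wp}


def default_ks(usda_class: str) -> float:
    """Carsel & Parrish class-mean saturated conductivity, cm/d."""
    try:
        return CARSEL_PARRISH[usda_class]["ks"]
    except KeyError:
        raise ValueError(f"unknown USDA class {usda_class!r}") from None


def default_hydraulics(
    texture: SoilTexture,
    method: int = 9,
    theta_fc: Optional[float] = None,
    theta_wp: Optional[float] = None,
    ks: Optional[float] = None,
) -> SoilHydraulics:
    """Assemble a full :class:`SoilHydraulics` from texture.

    Measured ``theta_fc``/``theta_wp``/``ks`` override the pedotransfer and
    class-default values.  theta_res, theta_sat, alpha and n always come
    from the Carsel & Parrish class table (the retention-shape constants
    are not estimated by the Table-style regressions).
    """
    cls = classify_usda(texture)
    cp = CARSEL_PARRISH[cls]
    est = pedotransfer(texture, method)
    fc = theta_fc if theta_fc is not None else est["theta_fc"]
    wp = theta_wp if theta_wp is not None else est["theta_wp"]
    sat = est.get("theta_sat", cp["theta_sat"])
    sat = max(sat, fc + 1e-3)  # keep the ordering invariant when mixing sources
    return SoilHydraulics(
        theta_fc=fc,
        theta_wp=wp,
        theta_sat=sat,
        theta_res=min(cp["theta_res"], wp * 0.9),
        ks=ks if ks is not None else cp["ks"],
        vg_alpha=cp["vg_alpha"],
        vg_n=cp["vg_n"],
        usda_class=cls,
        bulk_density=est.get("bulk_density", texture.bulk_density),
    )


def relative_saturation(theta: float, hyd: SoilHydraulics) -> float:
    """Relative saturation S = (theta - theta_r)/(theta_s - theta_r) in [0, 1]."""
    if not (hyd.theta_res - 1e-12 <= theta <= hyd.theta_sat + 1e-12):
        raise ValueError(
            f"theta={theta} outside [theta_res={hyd.theta_res}, theta_sat={hyd.theta_sat}]"
        )
    s = (theta - hyd.theta_res) / (hyd.theta_sat - hyd.theta_res)
    return min(1.0, max(0.0, s))


def pressure_head(s: float, hyd: SoilHydraulics) -> float:
    """Invert the van Genuchten retention curve: head h (cm, >= 0) from S.

    S = [1/(1+(alpha*h)^n)]^m  =>  h = ((S^(-1/m) - 1)^(1/n))/alpha.
    """
    if not 0.0 < s <= 1.0:
        if s == 0.0:
            return math.inf
        raise ValueError(f"relative saturation must be in (0, 1], got {s}")
    m = hyd.vg_m
    return (s ** (-1.0 / m) - 1.0) ** (1.0 / hyd.vg_n) / hyd.vg_alpha


def hydraulic_conductivity(
    theta: float, hyd: SoilHydraulics, standard_mualem: bool = False
) -> float:
    """Unsaturated conductivity K(theta) in cm/d.

    Default is the working form K = Ks*S*[1-(1-S^(1/m))]^2; with
    ``standard_mualem`` the textbook K = Ks*sqrt(S)*[1-(1-S^(1/m))^m]^2.
    """
    s = relative_saturation(theta, hyd)
    if s <= 0.0:
        return 0.0
    m = hyd.vg_m
    if standard_mualem:
        return hyd.ks * math.sqrt(s) * (1.0 - (1.0 - s ** (1.0 / m)) ** m) ** 2
    return hyd.ks * s * (1.0 - (1.0 - s ** (1.0 / m))) ** 2
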