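"""Reference evapotranspiration: FAO-56 Penman–Monteith, Priestley–Taylor,
Hargreaves–Samani, and the local calibration of the HS exponent / PT alpha.

All estimators work on :class:`~dripfert.weather.WeatherDay` records and
return mm/day for the FAO reference grass surface.  PM needs temperature,
humidity, wind and solar radiation; PT drops the aerodynamic term in favour
of a dimensionless multiplier ``alpha`` (calibratable, default 1.26); HS
needs only Tmin/Tmax plus computed extraterrestrial radiation.

``calibrate`` reproduces the site-calibration routine: for each of 1-5
years it finds the coefficient (E_H for HS, alpha for PT) minimising the
sum of squared differences between the *cumulative* ET0 curve of the
candidate model and the Penman–Monteith curve inside a julian-day window;
the adopted value is the mean of the per-year optima.  Goodness of fit is
reported as %RMSE of the *daily* values (RMSE / mean of the reference,
x100) — the objective and the report deliberately use different scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .weather import WeatherDay, WeatherSeries

__all__ = [
    "ET0Params",
    "ET0Estimate",
    "CalibrationResult",
    "extraterrestrial_radiation",
    "et0_pm",
    "et0_pt",
    "et0_hs",
    "et0_series",
    "calibrate",
    "pct_rmse",
]

SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
LAMBDA = 2.45  # latent heat of vaporization, MJ/kg
STEFAN_BOLTZMANN = 4.903e-9  # MJ K-4 m-2 day-1
PM_ALBEDO = 0.23  # fixed FAO-56 reference-surface albedo


@dataclass
class ET0Params:
    """Estimator configuration (site + empirical coefficients)."""

    method: Literal["station", "pm", "pt", "hs"] = "pm"
    latitude_deg: float = 41.46
    elevation_m: float = 76.0
    hs_ch: float = 0.0023
    hs_eh: float = 0.5
    hs_ct: float = 17.8
    pt_alpha: float = 1.26
    albedo: float = 0.24  # crop albedo used by the PT net radiation

    def __post_init__(self) -> None:
        if not 0.5 <= self.pt_alpha <= 2.6:
            raise ValueError(f"pt_alpha {self.pt_alpha} outside [0.5, 2.6]")
        if not 0.0 < self.albedo < 1.0:
            raise ValueError("albedo must be in (0, 1)")

    @property
    def latitude_rad(self) -> float:
        return math.radians(self.latitude_deg)


@dataclass
class ET0Estimate:
    """Daily value with the intermediates retained for audit."""

    et0: float
    ra: float
    rn: Optional[float] = None
    s: Optional[float] = None
    gamma: Optional[float] = None
    es: Optional[float] = None
    ea: Optional[float] = None
    g: float = 0.0


def extraterrestrial_radiation(julian_day: int, latitude_rad: float) -> float:
    """FAO-56 daily extraterrestrial radiation Ra, MJ m-2 day-1."""
    if abs(latitude_rad) >= math.radians(66.5):
        raise ValueError("polar latitudes (|lat| >= 66.5 deg) are not handled")
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * julian_day / 365.0)
    decl = 0.409 * math.sin(2.0 * math.pi * julian_day / 365.0 - 1.39)
    ws = math.acos(-math.tan(latitude_rad) * math.tan(decl))
    return (
        24.0 * 60.0 / math.pi * SOLAR_CONSTANT * dr
        * (
            ws * math.sin(latitude_rad) * math.sin(decl)
            + math.cos(latitude_rad) * math.cos(decl) * math.sin(ws)
        )
    )


def _svp(t: float) -> float:
    """Saturation vapour pressure, kPa."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def _slope_svp(t: float) -> float:
    return 4098.0 * _svp(t) / (t + 237.3) ** 2


def _psychrometric(elevation_m: float) -> float:
    p = 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26
    return 0.000665 * p


def _ea(day: WeatherDay) -> float:
    """Actual vapour pressure; falls back to e0(Tmin) when humidity is absent."""
    if day.rhmin is not None and day.rhmax is not None:
        return 0.5 * (
            _svp(day.tmin) * day.rhmax / 100.0 + _svp(day.tmax) * day.rhmin / 100.0
        )
    return _svp(day.tmin)


def _net_radiation(day: WeatherDay, params: ET0Params, albedo: float) -> float:
    """FAO-56 net radiation from measured solar radiation."""
    ra = extraterrestrial_radiation(day.julian_day, params.latitude_rad)
    rs = day.solar_rad
    assert rs is not None
    rns = (1.0 - albedo) * rs
    rso = (0.75 + 2e-5 * params.elevation_m) * ra
    rel = min(rs / rso, 1.0) if rso > 0 else 1.0
    ea = _ea(day)
    rnl = (
        STEFAN_BOLTZMANN
        * 0.5 * ((day.tmax + 273.16) ** 4 + (day.tmin + 273.16) ** 4)
        * (0.34 - 0.14 * math.sqrt(ea))
        * (1.35 * rel - 0.35)
    )
    return rns - rnl


class MissingWeatherError(ValueError):
    """A required meteorological field is absent for the chosen estimator."""


def et0_pm(day: WeatherDay, params: ET0Params) -> ET0Estimate:
    """FAO-56 daily Penman–Monteith reference ET0 (mm/day), G = 0."""
    missing = [
        n for n, v in (
            ("solar_rad", day.solar_rad), ("wind", day.wind),
            ("rhmin", day.rhmin), ("rhmax", day.rhmax),
        ) if v is None
    ]
    if missing:
        raise MissingWeatherError(
            f"Penman-Monteith needs {', '.join(missing)}; select the "
            "Priestley-Taylor (radiation only) or Hargreaves-Samani "
            "(temperature only) method instead"
        )
    t = day.tmean
    s = _slope_svp(t)
    gamma = _psychrometric(params.elevation_m)
    es = 0.5 * (_svp(day.tmax) + _svp(day.tmin))
    ea = _ea(day)
    rn = _net_radiation(day, params, PM_ALBEDO)
    g = 0.0
    u2 = day.wind
    num = 0.408 * s * (rn - g) + gamma * (900.0 / (t + 273.0)) * u2 * (es - ea)
    den = s + gamma * (1.0 + 0.34 * u2)
    ra = extraterrestrial_radiation(day.julian_day, params.latitude_rad)
    return ET0Estimate(et0=max(num / den, 0.0), ra=ra, rn=rn, s=s, gamma=gamma,
                       es=es, ea=ea, g=g)


def et0_pt(day: WeatherDay, params: ET0Params) -> ET0Estimate:
    """Priestley–Taylor ET0 = alpha * s/(s+gamma) * (Rn-G)/lambda, mm/day.

    Rn uses the configurable crop ``albedo`` (default 0.24); negative
    available energy floors the estimate at zero.
    """
    if day.solar_rad is None:
        raise MissingWeatherError(
            "Priestley-Taylor needs solar radiation; select Hargreaves-Samani instead"
        )
    t = day.tmean
    s = _slope_svp(t)
    gamma = _psychrometric(params.elevation_m)
    rn = _net_radiation(day, params, params.albedo)
    g = 0.0
    et0 = params.pt_alpha * (s / (s + gamma)) * max(rn - g, 0.0) / LAMBDA
    ra = extraterrestrial_radiation(day.julian_day, params.latitude_rad)
    return ET0Estimate(et0=et0, ra=ra, rn=rn, s=s, gamma=gamma, g=g)


def et0_hs(day: WeatherDay, params: ET0Params) -> ET0Estimate:
    """Hargreaves–Samani ET0 = C_H*(Tmax-Tmin)^E_H*(Tmean+C_T)*Ra_mm, mm/day.

    Ra enters as equivalent evaporation (Ra/lambda, mm/day).
    """
    ra = extraterrestrial_radiation(day.julian_day, params.latitude_rad)
    ra_mm = ra / LAMBDA
    dtr = max(day.tmax - day.tmin, 0.0)
    et0 = params.hs_ch * dtr**params.hs_eh * (day.tmean + params.hs_ct) * ra_mm
    return ET0Estimate(et0=max(et0, 0.0), ra=ra)


_ESTIMATORS: dict[str, Callable[[WeatherDay, ET0Params], ET0Estimate]] = {
    "pm": et0_pm,
    "pt": et0_pt,
    "hs": et0_hs,
}


def et0_series(series: WeatherSeries | Sequence[WeatherDay], params: ET0Params) -> np.ndarray:
    """Vector of daily ET0 (mm) for the configured method.

    A station-provided ET0 column bypasses all models when
    ``params.method == "station"``.
    """
    days = list(series)
    if params.method == "station":
        vals = []
        for d in days:
            if d.et0_station is None:
                raise MissingWeatherError(f"JD {d.julian_day}: no station ET0 value")
            vals.append(d.et0_station)
        return np.asarray(vals, dtype=float)
    est = _ESTIMATORS[params.method]
    return np.asarray([est(d, params).et0 for d in days], dtype=float)


def pct_rmse(estimates: Sequence[float], reference: Sequence[float]) -> float:
    """Percentage RMSE: 100*sqrt(mean((x_hat-x)^2))/mean(x), daily values."""
    x_hat = np.asarray(estimates, dtype=float)
    x = np.asarray(reference, dtype=float)
    if x.size == 0 or x_hat.size != x.size:
        raise ValueError("estimates and reference must be equal-length and non-empty")
    mean_ref = float(np.mean(x))
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * float(np.sqrt(np.mean((x_hat - x) ** 2))) / mean_ref


@dataclass
class CalibrationResult:
    target: Literal["hs_eh", "pt_alpha"]
    per_year: list[float]
    value: float  # mean of per-year optima: the adopted coefficient
    pct_rmse_before: float
    pct_rmse_after: float
    window: tuple[int, int] = (1, 366)
    extras: dict = field(default_factory=dict)


_BOUNDS = {"hs_eh": (0.3, 0.8), "pt_alpha": (0.5, 2.6)}


def calibrate(
    series_per_year: Sequence[WeatherSeries],
    target: Literal["hs_eh", "pt_alpha"],
    window: tuple[int, int],
    params: Optional[ET0Params] = None,
    reference: Optional[Callable[[WeatherSeries], np.ndarray]] = None,
) -> CalibrationResult:
    """Fit the HS exponent or the PT alpha against Penman–Monteith.

    For each year the objective is the SSE between the cumulative ET0
    curves of the candidate model and the reference inside ``window``;
    the adopted coefficient is the mean of the per-year optima.
    ``reference`` defaults to PM and exists so tests can plant a known
    coefficient as the target.
    """
    if not 1 <= len(series_per_year) <= 5:
        raise ValueError("calibration takes 1 to 5 years of weather")
    if target not in _BOUNDS:
        raise ValueError(f"target must be 'hs_eh' or 'pt_alpha', got {target!r}")
    params = params or ET0Params()
    start_jd, end_jd = window
    lo, hi = _BOUNDS[target]

    def candidate(series: WeatherSeries, coeff: float) -> np.ndarray:
        p = ET0Params(**{**params.__dict__, "method": "hs" if target == "hs_eh" else "pt"})
        setattr(p, target, coeff)
        return et0_series(series, p)

    def ref_values(series: WeatherSeries) -> np.ndarray:
        if reference is not None:
            return reference(series)
        return et0_series(series, ET0Params(**{**params.__dict__, "method": "pm"}))

    per_year: list[float] = []
    windows: list[tuple[np.ndarray, WeatherSeries]] = []
    for year in series_per_year:
        win = year.window(start_jd, end_jd)
        if len(win) == 0:
            raise ValueError(f"window {window} selects no days")
        ref = ref_values(win)
        windows.append((ref, win))

        def sse(coeff: float, _ref=ref, _win=win) -> float:
            diff = np.cumsum(candidate(_win, coeff)) - np.cumsum(_ref)
            return float(np.dot(diff, diff))

        res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        per_year.append(float(res.x))

    adopted = float(np.mean(per_year))
    default = getattr(params, target)
    daily_before, daily_after, daily_ref = [], [], []
    for ref, win in windows:
        daily_ref.append(ref)
        daily_before.append(candidate(win, default))
        daily_after.append(candidate(win, adopted))
    ref_all = np.concatenate(daily_ref)
    result = CalibrationResult(
        target=target,
        per_year=per_year,
        value=adopted,
        pct_rmse_before=pct_rmse(np.concatenate(daily_before), ref_all),
        pct_rmse_after=pct_rmse(np.concatenate(daily_after), ref_all),
        window=window,
    )
    return result
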