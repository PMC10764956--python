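"""Static-chamber gas fluxes and their CO2-equivalent expression.

A closed chamber placed on the soil surface accumulates (or depletes) N2O
and CH4 in its headspace; the concentration change over closure time,
converted with the ideal-gas law to a mass flux per unit area, gives the
soil-atmosphere exchange rate.  Fluxes sampled over a season are
integrated by linear interpolation to cumulative emissions, and the two
gases are combined into a single warming potential using 100-year
CO2-equivalent factors (N2O x 273, CH4 x 27).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: molecular mass of the trace gases, g/mol
MOLAR_MASS = {"N2O": 44.0, "CH4": 16.0}
#: molar volume of an ideal gas at standard temperature and pressure, m3/mol
MOLAR_VOLUME_STP = 0.022414
#: standard temperature, K
T_STANDARD = 273.15
#: standard pressure, kPa
P_STANDARD = 101.325
#: 100-year global warming potentials, kg CO2-eq per kg species
GWP_N2O = 273.0
GWP_CH4 = 27.0
#: unit bridge: 1 kg ha-1 h-1 equals 1e5 ug m-2 h-1
UG_M2_H_PER_KG_HA_H = 1.0e5


@dataclass(frozen=True)
class ChamberSeries:
    """One chamber closure: gas concentrations at successive minutes.

    Concentrations are in ppm (treated as numeric mixing ratios), closure
    times in minutes, chamber headspace temperature in K, pressure in kPa
    and chamber height in m.
    """

    plot: str
    day: float
    gas: str
    minutes: np.ndarray
    conc_ppm: np.ndarray
    temp_k: float
    pressure_kpa: float
    height_m: float

    def __post_init__(self) -> None:
        minutes = np.asarray(self.minutes, dtype=float)
        conc = np.asarray(self.conc_ppm, dtype=float)
        object.__setattr__(self, "minutes", minutes)
        object.__setattr__(self, "conc_ppm", conc)
        if self.gas not in MOLAR_MASS:
            raise ValueError(f"unknown gas {self.gas!r}; expected one of {sorted(MOLAR_MASS)}")
        if minutes.size < 3:
            raise ValueError("chamber series needs at least 3 time points")
        if minutes.size != conc.size:
            raise ValueError("minutes and concentrations differ in length")
        if not np.all(np.diff(minutes) > 0):
            raise ValueError("closure times must be strictly increasing")
        if self.temp_k <= 0 or self.pressure_kpa <= 0 or self.height_m <= 0:
            raise ValueError("temperature, pressure and chamber height must be positive")


@dataclass(frozen=True)
class FluxFit:
    """OLS fit of headspace concentration against closure time."""

    slope_ppm_min: float
    intercept_ppm: float
    r_squared: float
    flux_ug_m2_h: float

    @property
    def flux_kg_ha_h(self) -> float:
        return self.flux_ug_m2_h / UG_M2_H_PER_KG_HA_H


def flux_coefficient(gas: str, temp_k: float, pressure_kpa: float, height_m: float) -> float:
    """Factor converting a ppm/min headspace slope to a flux in ug m-2 h-1.

    (M/V0) * (T0/T) * (P/P0) * H * 60, the ideal-gas density of the gas at
    chamber conditions times chamber height and a minutes-to-hours factor.
    """
    if gas not in MOLAR_MASS:
        raise ValueError(f"unknown gas {gas!r}")
    if temp_k <= 0 or pressure_kpa <= 0 or height_m <= 0:
        raise ValueError("temperature, pressure and chamber height must be positive")
    return (
        MOLAR_MASS[gas]
        / MOLAR_VOLUME_STP
        * (T_STANDARD / temp_k)
        * (pressure_kpa / P_STANDARD)
        * height_m
        * 60.0
    )


def fit_flux(series: ChamberSeries, r2_min: float | None = None) -> FluxFit:
    """Estimate the soil flux of one chamber closure.

    The headspace slope d_c/d_t comes from ordinary least squares of
    concentration on closure minutes; negative slopes (CH4 uptake) are
    legitimate.  ``r2_min`` optionally rejects poor linear fits, a common
    chamber QC step that is off by default.
    """
    if np.ptp(series.minutes) == 0:
        raise ValueError("zero time span in chamber series")
    res = stats.linregress(series.minutes, series.conc_ppm)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    if r2_min is not None and r2 < r2_min:
        raise ValueError(
            f"chamber fit R^2 {r2:.3f} below threshold {r2_min:.3f} "
            f"(plot {series.plot}, day {series.day}, {series.gas})"
        )
    coef = flux_coefficient(series.gas, series.temp_k, series.pressure_kpa, series.height_m)
    return FluxFit(
        slope_ppm_min=float(res.slope),
        intercept_ppm=float(res.intercept),
        r_squared=r2,
        flux_ug_m2_h=float(res.slope) * coef,
    )


def fit_flux_table(chamber: pd.DataFrame, r2_min: float | None = None) -> pd.DataFrame:
    """Vectorized :func:`fit_flux` over a long chamber table.

    ``chamber`` has one row per (plot, day, gas, closure minute) with
    columns plot, day, gas, t_min, conc_ppm, temp_k, pressure_kpa,
    height_m.  Returns one row per chamber closure with the fitted slope,
    R^2 and the flux in both unit views.
    """
    required = {"plot", "day", "gas", "t_min", "conc_ppm", "temp_k", "pressure_kpa", "height_m"}
    missing = required - set(chamber.columns)
    if missing:
        raise ValueError(f"chamber table missing columns {sorted(missing)}")
    keys = ["plot", "day", "gas"]
    g = chamber.groupby(keys, sort=True)
    n = g.size()
    if (n < 3).any():
        raise ValueError("every chamber closure needs at least 3 time points")
    t = chamber["t_min"].astype(float)
    c = chamber["conc_ppm"].astype(float)
    st = t.groupby([chamber[k] for k in keys]).sum()
    sc = c.groupby([chamber[k] for k in keys]).sum()
    stt = (t * t).groupby([chamber[k] for k in keys]).sum()
    stc = (t * c).groupby([chamber[k] for k in keys]).sum()
    scc = (c * c).groupby([chamber[k] for k in keys]).sum()
    var_t = stt - st * st / n
    if (var_t <= 0).any():
        raise ValueError("zero time span in at least one chamber series")
    cov_tc = stc - st * sc / n
    var_c = scc - sc * sc / n
    slope = cov_tc / var_t
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(var_c > 0, cov_tc**2 / (var_t * var_c), 1.0)
    meta = g[["temp_k", "pressure_kpa", "height_m"]].first()
    out = meta.reset_index()
    coef = np.array(
        [
            flux_coefficient(gas, tk, pk, hm)
            for gas, tk, pk, hm in zip(
                out["gas"], out["temp_k"], out["pressure_kpa"], out["height_m"]
            )
        ]
    )
    out["slope_ppm_min"] = slope.to_numpy()
    out["r_squared"] = r2
    out["flux_ug_m2_h"] = out["slope_ppm_min"] * coef
    out["flux_kg_ha_h"] = out["flux_ug_m2_h"] / UG_M2_H_PER_KG_HA_H
    if r2_min is not None:
        out = out[out["r_squared"] >= r2_min].reset_index(drop=True)
    return out


@dataclass(frozen=True)
class FluxSeries:
    """Ordered (day, flux) samples for one plot and gas."""

    plot: str
    gas: str
    days: np.ndarray
    flux_kg_ha_h: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        flux = np.asarray(self.flux_kg_ha_h, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "flux_kg_ha_h", flux)
        if days.size != flux.size:
            raise ValueError("days and fluxes differ in length")
        if days.size and not np.all(np.diff(days) > 0):
            raise ValueError("sampling days must be strictly increasing")

    @property
    def flux_ug_m2_h(self) -> np.ndarray:
        return self.flux_kg_ha_h * UG_M2_H_PER_KG_HA_H


def cumulative_emission(
    series: FluxSeries, window: tuple[float, float] | None = None
) -> float:
    """Cumulative emission in kg/ha by trapezoidal (linear-interpolation) integration.

    Fluxes in kg ha-1 h-1 against sampling times in days, times 24 h/day.
    ``window`` clips the series to [t_start, t_end], interpolating the
    flux at the boundaries.
    """
    days, flux = series.days, series.flux_kg_ha_h
    if window is not None:
        lo, hi = window
        if hi <= lo:
            raise ValueError("window end must exceed window start")
        lo = max(lo, days.min()) if days.size else lo
        hi = min(hi, days.max()) if days.size else hi
        inside = (days > lo) & (days < hi)
        days_w = np.concatenate([[lo], days[inside], [hi]])
        flux_w = np.concatenate(
            [[np.interp(lo, days, flux)], flux[inside], [np.interp(hi, days, flux)]]
        )
        days, flux = days_w, flux_w
    if days.size < 2:
        raise ValueError("cumulative emission needs at least 2 samplings in the window")
    return float(np.trapezoid(flux, days) * 24.0)


def gwp(
    n2o_cum_kg_ha: float,
    ch4_cum_kg_ha: float,
    gwp_n2o: float = GWP_N2O,
    gwp_ch4: float = GWP_CH4,
) -> float:
    """Combined warming potential of soil N2O and CH4, kg CO2-eq/ha.

    Inputs are cumulative *species* masses (kg N2O and kg CH4, not element
    masses).  A negative CH4 term (soil methane sink) reduces the total.
    """
    return n2o_cum_kg_ha * gwp_n2o + ch4_cum_kg_ha * gwp_ch4


def n_basis_to_species(n2o_n_kg_ha: float) -> float:
    """Convert an N2O emission reported as kg N/ha to kg N2O/ha (x 44/28)."""
    if n2o_n_kg_ha < 0:
        raise ValueError("N2O-N emission must be nonnegative")
    return n2o_n_kg_ha * 44.0 / 28.0


def species_to_n_basis(n2o_kg_ha: float) -> float:
    """Convert kg N2O/ha to the nitrogen basis kg N/ha (x 28/44)."""
    return n2o_kg_ha * 28.0 / 44.0
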