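"""Indirect emissions, soil organic carbon stocks, and the net GHG balance.

The net greenhouse-gas balance of a rotation is the life-cycle (indirect)
emissions of its agricultural inputs, plus the warming potential of its
soil N2O/CH4 fluxes, minus the CO2-equivalent of soil carbon it
sequesters:

    net = CE + GWP(N2O+CH4) - dC

with every term in kg CO2-eq ha-1 yr-1 and dC positive when the soil is a
carbon sink.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: mass conversion from C to CO2
C_TO_CO2 = 44.0 / 12.0


def indirect_emissions(
    inventory: Mapping[str, float] | pd.DataFrame,
    factors: Mapping[str, float],
    cycle_years: float = 1.0,
) -> float:
    """Life-cycle emissions of agricultural inputs, kg CO2-eq/ha/yr.

    ``inventory`` maps input kinds (kg N, kg P2O5, L diesel, kWh
    electricity, ...) to amounts per cycle in the factor table's native
    units; ``factors`` maps the same kinds to kg CO2-eq per unit.  The
    cycle total Sum_k D_k * C_k is annualized by ``cycle_years``.
    """
    if cycle_years <= 0:
        raise ValueError("cycle_years must be positive")
    if isinstance(inventory, pd.DataFrame):
        items: Iterable[tuple[str, float]] = zip(inventory["input_kind"], inventory["amount"])
    else:
        items = inventory.items()
    total = 0.0
    for kind, amount in items:
        if amount < 0:
            raise ValueError(f"negative amount for input kind {kind!r}")
        if kind not in factors:
            raise KeyError(f"no emission factor for input kind {kind!r}")
        total += amount * factors[kind]
    return total / cycle_years


@dataclass(frozen=True)
class SoilLayer:
    top_cm: float
    bottom_cm: float
    soc_g_kg: float
    bd_g_cm3: float

    @property
    def thickness_cm(self) -> float:
        return self.bottom_cm - self.top_cm


@dataclass(frozen=True)
class SoilProfile:
    """Layered SOC concentration / bulk density profile of one plot."""

    plot: str
    timepoint: int
    layers: tuple[SoilLayer, ...]

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        if not layers:
            raise ValueError("soil profile has no layers")
        prev_bottom = layers[0].top_cm
        for layer in layers:
            if layer.bottom_cm <= layer.top_cm:
                raise ValueError("layer bottom must exceed its top")
            if layer.top_cm != prev_bottom:
                raise ValueError("layers must be contiguous and ordered by depth")
            if layer.soc_g_kg <= 0 or layer.bd_g_cm3 <= 0:
                raise ValueError("SOC concentration and bulk density must be positive")
            prev_bottom = layer.bottom_cm

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SoilProfile":
        """Build a profile from rows with plot, timepoint, top_cm, bottom_cm, soc_g_kg, bd_g_cm3."""
        frame = frame.sort_values("top_cm")
        plot = str(frame["plot"].iloc[0])
        timepoint = int(frame["timepoint"].iloc[0])
        layers = tuple(
            SoilLayer(r.top_cm, r.bottom_cm, r.soc_g_kg, r.bd_g_cm3)
            for r in frame.itertuples()
        )
        return cls(plot=plot, timepoint=timepoint, layers=layers)


def layer_stocks(profile: SoilProfile) -> np.ndarray:
    """Per-layer SOC stock, t C/ha: conc (g/kg) * BD (g/cm3) * thickness (cm) * 0.1."""
    return np.array(
        [lay.soc_g_kg * lay.bd_g_cm3 * lay.thickness_cm * 0.1 for lay in profile.layers]
    )


def soc_stock(profile: SoilProfile) -> float:
    """Whole-profile SOC stock in t C/ha."""
    return float(layer_stocks(profile).sum())


def depth_shares(profile: SoilProfile, boundaries_cm: Iterable[float] = (20, 30, 50)) -> dict[float, float]:
    """Cumulative stock fraction above each depth boundary (e.g. 0-20 / 0-90).

    Boundaries must coincide with layer interfaces.
    """
    stocks = layer_stocks(profile)
    total = stocks.sum()
    bottoms = [lay.bottom_cm for lay in profile.layers]
    shares = {}
    for b in boundaries_cm:
        if b not in bottoms:
            raise ValueError(f"depth {b} cm is not a layer boundary of the profile")
        idx = bottoms.index(b)
        shares[float(b)] = float(stocks[: idx + 1].sum() / total)
    return shares


@dataclass(frozen=True)
class DeltaSOC:
    """Annualized soil carbon stock change over the study period."""

    rate_t_c_ha_yr: float
    co2e_kg_ha_yr: float


def delta_soc(stock_start_t_ha: float, stock_end_t_ha: float, n_years: float) -> DeltaSOC:
    """Annual SOC change between two stock measurements.

    Positive values mean the soil accrued carbon (a sink).  Returned both
    as a carbon-basis rate (t C/ha/yr) and as kg CO2-eq/ha/yr via the
    44/12 C-to-CO2 mass ratio.
    """
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    rate = (stock_end_t_ha - stock_start_t_ha) / n_years
    return DeltaSOC(rate_t_c_ha_yr=rate, co2e_kg_ha_yr=rate * C_TO_CO2 * 1000.0)


@dataclass(frozen=True)
class GHGBudget:
    """Net GHG balance of one rotation, kg CO2-eq/ha/yr."""

    ce: float
    gwp: float
    delta_c: float
    net: float
    offset_fraction: float | None

    def __post_init__(self) -> None:
        if self.net != self.ce + self.gwp - self.delta_c:
            raise ValueError("budget identity net = CE + GWP - dC violated")


def net_ghg(ce: float, gwp_value: float, delta_c: float) -> GHGBudget:
    """Combine the three budget terms; offset fraction is dC / (CE + GWP)."""
    gross = ce + gwp_value
    offset = delta_c / gross if gross > 0 else None
    return GHGBudget(
        ce=ce,
        gwp=gwp_value,
        delta_c=delta_c,
        net=ce + gwp_value - delta_c,
        offset_fraction=offset,
    )
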