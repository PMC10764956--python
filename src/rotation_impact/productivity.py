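"""Productivity metrics: equivalent yield, economic benefit, protein and nutrition yield.

Crops in a rotation trial differ in product type (grain, tuber, silage),
so yields are compared after re-expressing each crop in wheat-equivalent
units via its market price relative to winter wheat.  Net income is
deflated with a consumer price index to a common base year, and protein
yield applies a per-crop protein fraction.  Rotation-cycle totals are
annualized by cycle length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PriceIndex:
    """Consumer price index by year with a deflation base year."""

    cpi: Mapping[int, float]
    base_year: int = 2008

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.cpi.values()):
            raise ValueError("CPI values must be positive")
        if self.base_year not in self.cpi:
            raise ValueError(f"CPI value for base year {self.base_year} missing")

    def deflator(self, year: int) -> float:
        """CPI_year / CPI_base."""
        if year not in self.cpi:
            raise KeyError(f"CPI value for year {year} missing")
        return self.cpi[year] / self.cpi[self.base_year]


def equivalent_yield(yield_kg_ha: float, price: float, wheat_price: float) -> float:
    """Wheat-equivalent yield, kg/ha: yield times the price ratio to wheat."""
    if wheat_price <= 0:
        raise ValueError("wheat price must be positive")
    return yield_kg_ha * price / wheat_price


def economic_benefit(
    yield_kg_ha: float,
    price: float,
    cpi: PriceIndex,
    year: int,
    cost: float,
) -> float:
    """CPI-deflated net income, currency/ha: yield x price x CPI_j/CPI_base - cost."""
    return yield_kg_ha * price * cpi.deflator(year) - cost


def protein_yield(yield_kg_ha: float, beta: float) -> float:
    """Protein yield, kg/ha, from the crop's protein mass fraction beta."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("protein fraction beta must lie in [0, 1]")
    return yield_kg_ha * beta


def dry_matter_yield(yield_kg_ha: float, moisture_fraction: float) -> float:
    """Convert a commercial-moisture yield to a dry-matter basis."""
    if not 0.0 <= moisture_fraction < 1.0:
        raise ValueError("moisture fraction must lie in [0, 1)")
    return yield_kg_ha * (1.0 - moisture_fraction)


def annualize_rotation(records: pd.DataFrame, cycle_years: float) -> dict[str, float]:
    """Annualize cycle totals of already-computed per-crop metrics.

    ``records`` holds the crop rows of exactly one rotation cycle with
    columns ``ey``, ``eb``, ``pc`` (fallow seasons simply contribute no
    rows).  Returns cycle sums divided by ``cycle_years``.
    """
    if cycle_years <= 0:
        raise ValueError("cycle_years must be positive")
    if "rotation" in records.columns and records["rotation"].nunique() > 1:
        raise ValueError("records mix several rotations; annualize one rotation at a time")
    out = {}
    for col in ("ey", "eb", "pc"):
        out[col] = float(records[col].sum()) / cycle_years if len(records) else 0.0
    return out


def crop_metrics(
    records: pd.DataFrame,
    cpi: PriceIndex,
    wheat_price_by_year: Mapping[int, float],
) -> pd.DataFrame:
    """Add per-crop ey/eb/pc columns to a crop-record table.

    ``records`` columns: plot, rotation, year, crop, yield_kg_ha,
    price_yuan_kg, cost_yuan_ha, protein_fraction.
    """
    out = records.copy()
    wheat_price = out["year"].map(dict(wheat_price_by_year))
    if wheat_price.isna().any():
        missing = sorted(out.loc[wheat_price.isna(), "year"].unique())
        raise KeyError(f"no wheat price for years {missing}")
    out["ey"] = [
        equivalent_yield(y, p, w)
        for y, p, w in zip(out["yield_kg_ha"], out["price_yuan_kg"], wheat_price)
    ]
    out["eb"] = [
        economic_benefit(y, p, cpi, int(j), c)
        for y, p, j, c in zip(
            out["yield_kg_ha"], out["price_yuan_kg"], out["year"], out["cost_yuan_ha"]
        )
    ]
    out["pc"] = [
        protein_yield(y, b) for y, b in zip(out["yield_kg_ha"], out["protein_fraction"])
    ]
    return out


def nutrition_yield(
    crop_records: pd.DataFrame,
    nutrient_table: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
    annual_years: float = 1.0,
) -> pd.Series:
    """Composite nutrition score per rotation from multi-nutrient yields.

    For each rotation, the per-nutrient annual yield is the sum over its
    crop records of yield times the per-kg nutrient concentration (from
    ``nutrient_table``, crops x nutrients), divided by ``annual_years``.
    Each nutrient's rotation-level yield is then min-max normalized across
    rotations and the composite is their weighted average (equal weights
    by default).  A nutrient constant across rotations contributes 0.5.
    """
    missing = set(crop_records["crop"]) - set(nutrient_table.index)
    if missing:
        raise KeyError(f"crops missing from nutrient table: {sorted(missing)}")
    nutrients = list(nutrient_table.columns)
    if weights is None:
        weights = {n: 1.0 / len(nutrients) for n in nutrients}
    w = np.array([weights[n] for n in nutrients], dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("nutrient weights must sum to 1")

    conc = nutrient_table.loc[crop_records["crop"], nutrients].to_numpy()
    per_record = conc * crop_records["yield_kg_ha"].to_numpy()[:, None]
    per_rot = (
        pd.DataFrame(per_record, columns=nutrients, index=crop_records.index)
        .assign(rotation=crop_records["rotation"].to_numpy())
        .groupby("rotation")
        .sum()
        / annual_years
    )
    span = per_rot.max() - per_rot.min()
    normalized = (per_rot - per_rot.min()).div(span.replace(0.0, np.nan))
    normalized = normalized.fillna(0.5)
    return (normalized * w).sum(axis=1)
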