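"""End-to-end assessment pipeline for a rotation experiment.

Chains every stage on a (synthetic or loaded) experiment: productivity
metrics, chamber flux fitting and integration, the GHG budget, soil
health scoring, microbial alpha-diversity, the entropy-TOPSIS
comprehensive evaluation index, and the group statistics.  All stage
outputs are plain tables so each step is independently auditable; the
manifest records the config hash and seeds of the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from rotation_impact import carbon_budget as cb
from rotation_impact import ghg_flux as gf
from rotation_impact import mcda, productivity, soil_health
from rotation_impact.config import ExperimentConfig
from rotation_impact.diversity import alpha_diversity_table, rarefy
from rotation_impact.stats import GroupStats, correlation_matrix, group_stats
from rotation_impact.synthetic import DAYS_PER_YEAR, RotationDataset, child_rng, generate_dataset


@dataclass
class PipelineResult:
    dataset: RotationDataset
    tables: dict[str, pd.DataFrame]
    cei: mcda.CEIResult
    group_tests: dict[str, GroupStats]
    correlations: pd.DataFrame
    manifest: dict


def _productivity_stage(dataset: RotationDataset) -> tuple[pd.DataFrame, pd.Series]:
    config = dataset.config
    cpi = productivity.PriceIndex(config.econ.cpi, config.econ.cpi_base_year)
    wheat_price = config.econ.crops[config.econ.wheat_crop].price_yuan_kg
    years = range(config.start_year, config.start_year + config.n_years)
    recs = productivity.crop_metrics(
        dataset.crop_records, cpi, {y: wheat_price for y in years}
    )
    per_plot = (
        recs.groupby(["plot", "rotation"], as_index=False)[["ey", "eb", "pc"]].sum()
    )
    per_plot[["ey", "eb", "pc"]] /= config.n_years
    nutrient_table = pd.DataFrame(
        {crop: spec.nutrients for crop, spec in config.econ.crops.items()}
    ).T.fillna(0.0)
    nutrition = productivity.nutrition_yield(
        dataset.crop_records,
        nutrient_table,
        annual_years=float(config.n_years * config.n_replicates),
    )
    return per_plot, nutrition


def _flux_stage(dataset: RotationDataset) -> pd.DataFrame:
    """Fit all chamber closures and integrate to mean annual emissions per plot."""
    config = dataset.config
    fits = gf.fit_flux_table(dataset.chamber)
    rows = []
    for (plot, gas), grp in fits.groupby(["plot", "gas"]):
        grp = grp.sort_values("day")
        annual = []
        for y in range(config.n_years):
            in_year = grp[
                (grp["day"] >= y * DAYS_PER_YEAR) & (grp["day"] < (y + 1) * DAYS_PER_YEAR)
            ]
            series = gf.FluxSeries(
                plot=plot,
                gas=gas,
                days=in_year["day"].to_numpy(),
                flux_kg_ha_h=in_year["flux_kg_ha_h"].to_numpy(),
            )
            annual.append(gf.cumulative_emission(series))
        rows.append({"plot": plot, "gas": gas, "annual_kg_ha": float(np.mean(annual))})
    wide = pd.DataFrame(rows).pivot(index="plot", columns="gas", values="annual_kg_ha")
    out = pd.DataFrame(
        {
            "n2o_kg_ha_yr": wide["N2O"],
            "n2o_n_kg_ha_yr": [gf.species_to_n_basis(v) for v in wide["N2O"]],
            "ch4_kg_ha_yr": wide["CH4"],
        }
    )
    out["gwp_kg_co2e_ha_yr"] = [
        gf.gwp(n2o, ch4) for n2o, ch4 in zip(out["n2o_kg_ha_yr"], out["ch4_kg_ha_yr"])
    ]
    return out.reset_index()


def _budget_stage(dataset: RotationDataset, flux_annual: pd.DataFrame) -> pd.DataFrame:
    config = dataset.config
    ce_by_rot = {
        rot.id: cb.indirect_emissions(config.inventories[rot.id], config.emission_factors)
        for rot in config.rotations
    }
    rows = []
    for (plot,), grp in dataset.soil_profiles.groupby(["plot"]):
        rotation = grp["rotation"].iloc[0]
        tps = sorted(grp["timepoint"].unique())
        p1 = cb.SoilProfile.from_frame(grp[grp["timepoint"] == tps[0]])
        p2 = cb.SoilProfile.from_frame(grp[grp["timepoint"] == tps[-1]])
        dsoc = cb.delta_soc(cb.soc_stock(p1), cb.soc_stock(p2), config.n_years)
        gwp_val = float(
            flux_annual.loc[flux_annual["plot"] == plot, "gwp_kg_co2e_ha_yr"].iloc[0]
        )
        budget = cb.net_ghg(ce_by_rot[rotation], gwp_val, dsoc.co2e_kg_ha_yr)
        assert budget.net == budget.ce + budget.gwp - budget.delta_c
        rows.append(
            {
                "plot": plot,
                "rotation": rotation,
                "ce_kg_co2e_ha_yr": budget.ce,
                "gwp_kg_co2e_ha_yr": budget.gwp,
                "delta_c_kg_co2e_ha_yr": budget.delta_c,
                "soc_rate_t_c_ha_yr": dsoc.rate_t_c_ha_yr,
                "net_kg_co2e_ha_yr": budget.net,
                "offset_fraction": budget.offset_fraction,
            }
        )
    return pd.DataFrame(rows)


def _soil_health_stage(dataset: RotationDataset) -> tuple[pd.DataFrame, pd.Series]:
    scores, weights, _report = soil_health.score_indicator_table(
        dataset.indicators[["plot", "timepoint", "indicator", "value"]]
    )
    scores = scores.reset_index().merge(
        dataset.plots[["plot", "rotation"]], on="plot", how="left"
    )
    return scores, weights


def _diversity_stage(dataset: RotationDataset, rarefy_seed: int) -> pd.DataFrame:
    parts = []
    for (marker, tp), table in sorted(dataset.otu_tables.items()):
        rng = child_rng(rarefy_seed, "rarefy", marker, tp)
        rarefied = rarefy(table, seed=rng)
        alpha = alpha_diversity_table(rarefied).reset_index()
        alpha.insert(0, "marker", marker)
        alpha.insert(1, "timepoint", tp)
        parts.append(alpha)
    out = pd.concat(parts, ignore_index=True).rename(columns={"sample": "plot"})
    return out.merge(dataset.plots[["plot", "rotation"]], on="plot", how="left")


def build_decision_matrix(
    per_plot_productivity: pd.DataFrame,
    nutrition: pd.Series,
    budget: pd.DataFrame,
    health_scores: pd.DataFrame,
    diversity: pd.DataFrame,
    final_timepoint: int,
) -> pd.DataFrame:
    """Rotation-level decision matrix of the seven assessment criteria.

    Criterion values are rotation means over the three replicate plots;
    soil biodiversity is the mean of the bacterial and fungal Shannon
    indices at the final timepoint.
    """
    prod = per_plot_productivity.groupby("rotation")[["ey", "eb"]].mean()
    bud = budget.groupby("rotation")[["soc_rate_t_c_ha_yr", "net_kg_co2e_ha_yr"]].mean()
    health = (
        health_scores[health_scores["timepoint"] == final_timepoint]
        .groupby("rotation")["overall"]
        .mean()
    )
    biodiv = (
        diversity[diversity["timepoint"] == final_timepoint]
        .groupby(["rotation", "plot"])["shannon"]
        .mean()  # mean over markers per plot
        .groupby("rotation")
        .mean()
    )
    matrix = pd.DataFrame(
        {
            "equivalent_yield": prod["ey"],
            "economic_benefit": prod["eb"],
            "nutrition_yield": nutrition,
            "soil_biodiversity": biodiv,
            "soil_health": health,
            "c_sequestration": bud["soc_rate_t_c_ha_yr"],
            "net_ghg": bud["net_kg_co2e_ha_yr"],
        }
    )
    return matrix.sort_index()


def run_pipeline(
    config: ExperimentConfig | None = None,
    dataset: RotationDataset | None = None,
    out_dir: str | Path | None = None,
    rarefy_seed: int | None = None,
) -> PipelineResult:
    """Run every assessment stage and return all tables plus the CEI ranking."""
    if dataset is None:
        dataset = generate_dataset(config)
    config = dataset.config
    if rarefy_seed is None:
        rarefy_seed = config.seed
    final_tp = config.start_year + config.n_years

    per_plot_prod, nutrition = _productivity_stage(dataset)
    flux_annual = _flux_stage(dataset)
    budget = _budget_stage(dataset, flux_annual)
    health_scores, health_weights = _soil_health_stage(dataset)
    diversity = _diversity_stage(dataset, rarefy_seed)
    matrix = build_decision_matrix(
        per_plot_prod, nutrition, budget, health_scores, diversity, final_tp
    )
    cei = mcda.cei_from_matrix(matrix)

    plot_metrics = (
        per_plot_prod.merge(budget.drop(columns="rotation"), on="plot")
        .merge(
            health_scores.loc[
                health_scores["timepoint"] == final_tp, ["plot", "overall"]
            ].rename(columns={"overall": "soil_health"}),
            on="plot",
        )
    )
    group_tests = {
        name: group_stats(plot_metrics, value=name, group="rotation")
        for name in ("ey", "eb", "net_kg_co2e_ha_yr", "soil_health")
    }
    # rotation-level Pearson correlations need >= 3 rotations to be defined
    if len(matrix) >= 3:
        correlations = correlation_matrix(matrix)
    else:
        correlations = pd.DataFrame(
            np.nan, index=matrix.columns, columns=matrix.columns
        )

    cei_table = pd.DataFrame(
        {
            "cei": cei.cei,
            "rank": cei.ranks,
            "d_plus": cei.distance_positive,
            "d_minus": cei.distance_negative,
        }
    )
    tables = {
        "productivity_plots": per_plot_prod,
        "nutrition": nutrition.rename("nutrition_yield").reset_index(),
        "flux_annual": flux_annual,
        "budget": budget,
        "soil_health_scores": health_scores,
        "soil_health_weights": health_weights.rename("weight").reset_index(),
        "diversity": diversity,
        "decision_matrix": matrix.reset_index(),
        "cei": cei_table.reset_index(),
    }
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "rarefy_seed": rarefy_seed,
        "n_plots": int(len(dataset.plots)),
        "n_years": config.n_years,
        "entropy_weights": {k: float(v) for k, v in cei.weights.items()},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        correlations.to_csv(out / "correlations.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        dataset=dataset,
        tables=tables,
        cei=cei,
        group_tests=group_tests,
        correlations=correlations,
        manifest=manifest,
    )
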