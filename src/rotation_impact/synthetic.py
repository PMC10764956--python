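"""Synthetic rotation-trial generator.

Emulates the data streams of a six-year randomized complete block
rotation trial: per-plot crop records, weekly static-chamber N2O/CH4
concentration series with fertilization pulses, two-timepoint layered
SOC/bulk-density profiles, a ten-indicator topsoil table, and
two-timepoint OTU count tables for two gene markers.  Every stream is
calibrated so the configured ground truth (annual N2O-N, CH4 sink, soil C
accrual, diversity shift, crop yields) is recoverable by the downstream
pipeline stages, and every stream is reproducible from a single seed.

Seeding scheme: the global seed expands into independent child streams
via ``numpy.random.SeedSequence([seed, crc32(key_0), crc32(key_1), ...])``
where the keys name the stream (e.g. ``("flux", plot, year, gas)``), so
any one stream can be regenerated in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from rotation_impact.config import WHEAT_MAIZE_YEAR, ExperimentConfig, RotationSpec
from rotation_impact.ghg_flux import (
    UG_M2_H_PER_KG_HA_H,
    flux_coefficient,
    n_basis_to_species,
)

DAYS_PER_YEAR = 365
#: day-of-rotation-year (origin October) at which chamber air is warmest
_SEASON_PHASE_DAYS = 178.75


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic child generator for a named stream of the experiment."""
    entropy = [int(seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class ManagementCalendar:
    """Fertilization and precipitation days (relative to the rotation year)."""

    fertilization_days: tuple[int, ...]
    precipitation_days: tuple[int, ...] = ()
    season: tuple[int, int] = (0, DAYS_PER_YEAR)

    def __post_init__(self) -> None:
        if not self.fertilization_days and not self.precipitation_days:
            raise ValueError("management calendar has no events")


def _calendar_for_year(
    rotation: RotationSpec, year_index: int, rng: np.random.Generator
) -> ManagementCalendar:
    """Fertilization pattern for the crops grown that year (year starts in October)."""
    crops = rotation.crops_by_year[year_index % rotation.cycle_years]
    if crops == WHEAT_MAIZE_YEAR:
        fert = (10, 170, 250, 285)  # wheat basal + topdress, maize basal + topdress
    elif len(crops) == 2:
        fert = (15, 120, 200, 260)  # two short-season crops
    else:
        fert = (185, 230)  # single spring-sown crop
    precip = tuple(sorted(rng.choice(np.arange(150, 340), size=6, replace=False)))
    return ManagementCalendar(fertilization_days=fert, precipitation_days=precip)


def _sampling_days(calendar: ManagementCalendar, interval: int, lag: int) -> np.ndarray:
    weekly = np.arange(0, DAYS_PER_YEAR, interval)
    extra = np.array([d + lag for d in calendar.fertilization_days], dtype=float)
    days = np.unique(np.concatenate([weekly.astype(float), extra]))
    return days[(days >= 0) & (days < DAYS_PER_YEAR)]


def _pulse_shape(days: np.ndarray, calendar: ManagementCalendar, half_life: float) -> np.ndarray:
    """Sum of unit-amplitude exponential pulses released at each fertilization."""
    lam = np.log(2.0) / half_life
    shape = np.zeros_like(days, dtype=float)
    for f in calendar.fertilization_days:
        dt = days - f
        shape += np.where(dt >= 0, np.exp(-lam * dt), 0.0)
    return shape


def _chamber_temp_k(days: np.ndarray, temp_mean: float, amplitude: float) -> np.ndarray:
    return temp_mean + amplitude * np.sin(
        2.0 * np.pi * (days - _SEASON_PHASE_DAYS) / DAYS_PER_YEAR
    )


def generate_flux_series(
    plot: str,
    year_index: int,
    calendar: ManagementCalendar,
    gas: str,
    flux_model,
    baseline_kg_ha_h: float,
    pulse_amplitude_kg_ha_h: float,
    noise_sd_kg_ha_h: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chamber concentration series for one plot-year and gas.

    The true flux on each sampling day is baseline + fertilization pulse
    (exponentially decaying) + Gaussian noise; it is inverted through the
    ideal-gas chamber relation to a ppm/min headspace slope, producing
    concentrations at the configured closure minutes.  Returns
    (chamber rows, true flux rows); chamber days are absolute experiment
    days.
    """
    if noise_sd_kg_ha_h < 0:
        raise ValueError("noise SD must be nonnegative")
    days = _sampling_days(
        calendar, flux_model.sampling_interval_days, flux_model.post_event_lag_days
    )
    flux = baseline_kg_ha_h + pulse_amplitude_kg_ha_h * _pulse_shape(
        days, calendar, flux_model.pulse_half_life_days
    )
    if noise_sd_kg_ha_h > 0:
        flux = flux + rng.normal(0.0, noise_sd_kg_ha_h, size=days.size)
    temp = _chamber_temp_k(days, flux_model.temp_mean_k, flux_model.temp_amplitude_k)
    ambient = flux_model.ambient_ppm[gas]
    minutes = np.asarray(flux_model.closure_minutes, dtype=float)
    # keep headspace concentrations positive over the closure
    coef = np.array(
        [
            flux_coefficient(gas, t, flux_model.pressure_kpa, flux_model.chamber_height_m)
            for t in temp
        ]
    )
    slope_floor = -0.95 * ambient / max(minutes.max(), 1.0)
    slope = np.maximum(flux * UG_M2_H_PER_KG_HA_H / coef, slope_floor)
    flux = slope * coef / UG_M2_H_PER_KG_HA_H

    abs_days = year_index * DAYS_PER_YEAR + days
    conc = ambient + slope[:, None] * minutes[None, :]
    conc_noise = flux_model.conc_noise_ppm.get(gas, 0.0)
    if conc_noise > 0:
        conc = conc + rng.normal(0.0, conc_noise, size=conc.shape)
    conc = np.maximum(conc, 1e-4)
    n_d, n_t = conc.shape
    chamber = pd.DataFrame(
        {
            "plot": plot,
            "day": np.repeat(abs_days, n_t),
            "gas": gas,
            "t_min": np.tile(minutes, n_d),
            "conc_ppm": conc.ravel(),
            "temp_k": np.repeat(temp, n_t),
            "pressure_kpa": flux_model.pressure_kpa,
            "height_m": flux_model.chamber_height_m,
        }
    )
    truth = pd.DataFrame(
        {"plot": plot, "day": abs_days, "gas": gas, "true_flux_kg_ha_h": flux}
    )
    return chamber, truth


def _calibrated_flux_params(
    rotation: RotationSpec, gas: str, calendar: ManagementCalendar, flux_model
) -> tuple[float, float, float]:
    """Baseline, pulse amplitude and noise SD (kg/ha/h) hitting the annual target.

    The deterministic flux shape is integrated with the same trapezoid
    rule the analysis uses, and scaled so the annual cumulative equals the
    rotation's configured target (N2O target configured on the N basis,
    generated as species mass; CH4 a species-mass sink).
    """
    days = _sampling_days(
        calendar, flux_model.sampling_interval_days, flux_model.post_event_lag_days
    )
    if gas == "N2O":
        target_kg = n_basis_to_species(rotation.n2o_n_annual_kg_ha)
        shape = 1.0 + flux_model.pulse_amplitude_ratio * _pulse_shape(
            days, calendar, flux_model.pulse_half_life_days
        )
    else:
        target_kg = rotation.ch4_annual_kg_ha
        shape = np.ones_like(days, dtype=float)
    raw = float(np.trapezoid(shape, days) * 24.0)  # kg/ha per unit baseline
    baseline = target_kg / raw if raw != 0 else 0.0
    pulse_amp = (
        baseline * flux_model.pulse_amplitude_ratio if gas == "N2O" else 0.0
    )
    mean_flux = abs(target_kg) / (DAYS_PER_YEAR * 24.0)
    noise_sd = flux_model.noise_sd_fraction * mean_flux
    return baseline, pulse_amp, noise_sd


def shannon_of_lognormal_profile(sigma: float, n_taxa: int) -> float:
    """Shannon H of the deterministic quantile profile of a log-normal community."""
    z = norm.ppf((np.arange(1, n_taxa + 1) - 0.5) / n_taxa)
    a = sigma * z
    a -= a.max()
    p = np.exp(a)
    p /= p.sum()
    return float(-np.sum(p * np.log(p)))


def sigma_for_shift(sigma: float, n_taxa: int, shift: float) -> float:
    """Log-normal shape giving a relative Shannon change of ``shift``.

    A positive shift (higher diversity) narrows the abundance
    distribution; solved numerically on the deterministic quantile
    profile, where H is monotone decreasing in sigma.
    """
    if shift == 0.0:
        return sigma
    target = (1.0 + shift) * shannon_of_lognormal_profile(sigma, n_taxa)
    if target > np.log(n_taxa):
        raise ValueError("diversity shift exceeds the maximum attainable Shannon index")
    return float(
        brentq(
            lambda s: shannon_of_lognormal_profile(s, n_taxa) - target,
            1e-3,
            max(10.0, 5.0 * sigma),
            xtol=1e-10,
        )
    )


@dataclass
class RotationDataset:
    """The complete synthetic experiment, one table per data stream."""

    config: ExperimentConfig
    plots: pd.DataFrame
    crop_records: pd.DataFrame
    chamber: pd.DataFrame
    management: pd.DataFrame
    soil_profiles: pd.DataFrame
    indicators: pd.DataFrame
    otu_tables: dict[tuple[str, int], pd.DataFrame]
    ground_truth: dict = field(default_factory=dict)

    def to_dir(self, out_dir: str | Path) -> Path:
        """Write the dataset as CSV/TSV tables plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.plots.to_csv(out / "plots.csv", index=False)
        self.crop_records.to_csv(out / "crop_records.csv", index=False)
        self.chamber.to_csv(out / "chamber.csv", index=False)
        self.management.to_csv(out / "management.csv", index=False)
        self.soil_profiles.to_csv(out / "soil_profiles.csv", index=False)
        self.indicators.to_csv(out / "indicators.csv", index=False)
        for (marker, tp), table in self.otu_tables.items():
            table.to_csv(out / f"otu_{marker}_{tp}.tsv", sep="\t", index_label="taxon_id")
        truth = {
            k: (v.to_dict(orient="list") if isinstance(v, pd.DataFrame) else v)
            for k, v in self.ground_truth.items()
        }
        manifest = {
            "config": self.config.model_dump(mode="json"),
            "config_hash": self.config.config_hash(),
            "otu_tables": sorted(f"otu_{m}_{t}.tsv" for m, t in self.otu_tables),
            "ground_truth": truth,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return out

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "RotationDataset":
        src = Path(in_dir)
        manifest = json.loads((src / "manifest.json").read_text())
        config = ExperimentConfig.model_validate(manifest["config"])
        otu_tables = {}
        for name in manifest["otu_tables"]:
            marker, tp = name[len("otu_") : -len(".tsv")].rsplit("_", 1)
            otu_tables[(marker, int(tp))] = pd.read_csv(
                src / name, sep="\t", index_col="taxon_id"
            )
        truth = {
            k: (pd.DataFrame(v) if isinstance(v, dict) and "plot" in v else v)
            for k, v in manifest["ground_truth"].items()
        }
        return cls(
            config=config,
            plots=pd.read_csv(src / "plots.csv"),
            crop_records=pd.read_csv(src / "crop_records.csv"),
            chamber=pd.read_csv(src / "chamber.csv"),
            management=pd.read_csv(src / "management.csv"),
            soil_profiles=pd.read_csv(src / "soil_profiles.csv"),
            indicators=pd.read_csv(src / "indicators.csv"),
            otu_tables=otu_tables,
            ground_truth=truth,
        )


def _generate_design(config: ExperimentConfig) -> pd.DataFrame:
    """Randomized complete block layout: every block holds every rotation once."""
    rng = child_rng(config.seed, "design")
    rows = []
    rot_ids = [r.id for r in config.rotations]
    for block in range(1, config.n_replicates + 1):
        order = rng.permutation(rot_ids)
        for position, rot_id in enumerate(order, start=1):
            rows.append(
                {
                    "plot": f"{rot_id}-{block}",
                    "block": block,
                    "position": position,
                    "rotation": rot_id,
                }
            )
    return pd.DataFrame(rows).sort_values(["block", "position"]).reset_index(drop=True)


def _generate_crop_records(config: ExperimentConfig, plots: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for plot_row in plots.itertuples():
        rot = config.rotation(plot_row.rotation)
        rng = child_rng(config.seed, "crops", plot_row.plot)
        for y in range(config.n_years):
            crops = rot.crops_by_year[y % rot.cycle_years]
            boost = (
                1.0 + rot.carryover_boost
                if crops == WHEAT_MAIZE_YEAR and rot.cycle_years > 1
                else 1.0
            )
            for crop in crops:
                spec = config.econ.crops[crop]
                y_kg = spec.yield_mean_kg_ha * boost * max(
                    0.0, 1.0 + spec.yield_cv * rng.normal()
                )
                rows.append(
                    {
                        "plot": plot_row.plot,
                        "rotation": rot.id,
                        "year": config.start_year + y,
                        "crop": crop,
                        "yield_kg_ha": y_kg,
                        "price_yuan_kg": spec.price_yuan_kg,
                        "cost_yuan_ha": spec.cost_yuan_ha,
                        "protein_fraction": spec.protein_fraction,
                        "moisture_fraction": spec.moisture_fraction,
                    }
                )
    return pd.DataFrame(rows)


def _generate_flux_streams(
    config: ExperimentConfig, plots: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    chamber_parts, truth_parts, mgmt_rows = [], [], []
    calendars: dict[tuple[str, int], ManagementCalendar] = {}
    for rot in config.rotations:
        for y in range(config.n_years):
            cal = _calendar_for_year(rot, y, child_rng(config.seed, "calendar", rot.id, y))
            calendars[(rot.id, y)] = cal
            for d in cal.fertilization_days:
                mgmt_rows.append(
                    {"rotation": rot.id, "year": config.start_year + y, "event": "fertilization", "day": y * DAYS_PER_YEAR + d}
                )
            for d in cal.precipitation_days:
                mgmt_rows.append(
                    {"rotation": rot.id, "year": config.start_year + y, "event": "precipitation", "day": y * DAYS_PER_YEAR + d}
                )
    for plot_row in plots.itertuples():
        rot = config.rotation(plot_row.rotation)
        for y in range(config.n_years):
            cal = calendars[(rot.id, y)]
            for gas in ("N2O", "CH4"):
                base, amp, noise = _calibrated_flux_params(rot, gas, cal, config.flux)
                rng = child_rng(config.seed, "flux", plot_row.plot, y, gas)
                chamber, truth = generate_flux_series(
                    plot_row.plot, y, cal, gas, config.flux, base, amp, noise, rng
                )
                chamber_parts.append(chamber)
                truth_parts.append(truth)
    return (
        pd.concat(chamber_parts, ignore_index=True),
        pd.concat(truth_parts, ignore_index=True),
        pd.DataFrame(mgmt_rows),
    )


def _generate_soil_profiles(config: ExperimentConfig, plots: pd.DataFrame) -> pd.DataFrame:
    soil = config.soil
    tops = np.array([t for t, _ in soil.layers_cm])
    bottoms = np.array([b for _, b in soil.layers_cm])
    thick = bottoms - tops
    base_conc = np.asarray(soil.baseline_soc_g_kg)
    base_bd = np.asarray(soil.baseline_bd_g_cm3)
    shares = np.asarray(soil.accrual_depth_shares)
    t1, t2 = config.start_year, config.start_year + config.n_years
    rows = []
    for plot_row in plots.itertuples():
        rot = config.rotation(plot_row.rotation)
        rng = child_rng(config.seed, "soil", plot_row.plot)
        plot_conc = base_conc + rng.normal(0.0, soil.plot_sd_g_kg, size=base_conc.size)
        plot_bd = np.maximum(
            base_bd + rng.normal(0.0, soil.bd_sd_g_cm3, size=base_bd.size), 0.5
        )
        delta_stock = rot.soc_accrual_t_c_ha_yr * config.n_years * shares  # t C/ha per layer
        delta_conc = delta_stock / (plot_bd * thick * 0.1)
        for tp, conc in (
            (t1, plot_conc + rng.normal(0.0, soil.measurement_sd_g_kg, base_conc.size)),
            (t2, plot_conc + delta_conc + rng.normal(0.0, soil.measurement_sd_g_kg, base_conc.size)),
        ):
            conc = np.maximum(conc, 0.05)
            for i in range(tops.size):
                rows.append(
                    {
                        "plot": plot_row.plot,
                        "rotation": rot.id,
                        "timepoint": tp,
                        "top_cm": tops[i],
                        "bottom_cm": bottoms[i],
                        "soc_g_kg": conc[i],
                        "bd_g_cm3": plot_bd[i],
                    }
                )
    return pd.DataFrame(rows)


def _generate_indicators(config: ExperimentConfig, plots: pd.DataFrame) -> pd.DataFrame:
    t1, t2 = config.start_year, config.start_year + config.n_years
    rows = []
    for plot_row in plots.itertuples():
        rot = config.rotation(plot_row.rotation)
        rng = child_rng(config.seed, "indicators", plot_row.plot)
        for name, spec in config.soil.indicators.items():
            v1 = spec.mean + rng.normal(0.0, spec.sd)
            v2 = spec.mean + rot.indicator_effect * spec.response + rng.normal(0.0, spec.sd)
            rows.append({"plot": plot_row.plot, "rotation": rot.id, "timepoint": t1, "indicator": name, "value": v1})
            rows.append({"plot": plot_row.plot, "rotation": rot.id, "timepoint": t2, "indicator": name, "value": v2})
    return pd.DataFrame(rows)


def _generate_otu_tables(
    config: ExperimentConfig, plots: pd.DataFrame
) -> tuple[dict[tuple[str, int], pd.DataFrame], pd.DataFrame]:
    t1, t2 = config.start_year, config.start_year + config.n_years
    tables: dict[tuple[str, int], pd.DataFrame] = {}
    truth_rows = []
    for marker, mspec in config.otu.markers.items():
        taxa = [f"OTU{i:04d}" for i in range(1, mspec.n_taxa + 1)]
        for tp in (t1, t2):
            cols = {}
            for plot_row in plots.itertuples():
                rot = config.rotation(plot_row.rotation)
                sigma = (
                    mspec.lognormal_sigma
                    if tp == t1
                    else sigma_for_shift(mspec.lognormal_sigma, mspec.n_taxa, rot.shannon_shift)
                )
                rng = child_rng(config.seed, "otu", marker, tp, plot_row.plot)
                log_a = rng.normal(0.0, sigma, size=mspec.n_taxa)
                log_a -= log_a.max()
                p = np.exp(log_a)
                p /= p.sum()
                depth = max(
                    100, int(round(rng.normal(mspec.depth_mean, mspec.depth_cv * mspec.depth_mean)))
                )
                cols[plot_row.plot] = rng.multinomial(depth, p)
                truth_rows.append(
                    {
                        "marker": marker,
                        "timepoint": tp,
                        "plot": plot_row.plot,
                        "rotation": rot.id,
                        "sigma": sigma,
                        "true_shannon": float(-np.sum(p * np.log(p))),
                    }
                )
            tables[(marker, tp)] = pd.DataFrame(cols, index=pd.Index(taxa, name="taxon_id"))
    return tables, pd.DataFrame(truth_rows)


def generate_dataset(config: ExperimentConfig | None = None) -> RotationDataset:
    """Generate the full synthetic experiment for a configuration.

    Identical configurations (including the seed) produce bit-identical
    datasets.  The returned dataset carries its generating parameters in
    ``ground_truth`` for parameter-recovery testing.
    """
    config = ExperimentConfig() if config is None else config
    plots = _generate_design(config)
    crop_records = _generate_crop_records(config, plots)
    chamber, flux_truth, management = _generate_flux_streams(config, plots)
    soil_profiles = _generate_soil_profiles(config, plots)
    indicators = _generate_indicators(config, plots)
    otu_tables, shannon_truth = _generate_otu_tables(config, plots)
    targets = {
        rot.id: {
            "n2o_n_annual_kg_ha": rot.n2o_n_annual_kg_ha,
            "ch4_annual_kg_ha": rot.ch4_annual_kg_ha,
            "soc_accrual_t_c_ha_yr": rot.soc_accrual_t_c_ha_yr,
            "shannon_shift": rot.shannon_shift,
        }
        for rot in config.rotations
    }
    return RotationDataset(
        config=config,
        plots=plots,
        crop_records=crop_records,
        chamber=chamber,
        management=management,
        soil_profiles=soil_profiles,
        indicators=indicators,
        otu_tables=otu_tables,
        ground_truth={
            "targets": targets,
            "true_shannon": shannon_truth,
            "true_flux": flux_truth,
        },
    )
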