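"""Experiment configuration for the synthetic rotation trial.

The default configuration mirrors a six-rotation, three-replicate
randomized complete block trial run for six years on the North China
Plain: the conventional winter wheat-summer maize double crop (WM,
one-year cycle) against five two-year diversified rotations that insert
sweet potato (SpWM), peanut (PWM), soybean (SWM), spring maize (SmWM) or
a ryegrass-sorghum forage year (RSWM) ahead of the wheat-maize year.
Per-rotation targets (annual N2O-N, CH4 sink, soil C accrual, microbial
diversity shift) are the quantities the downstream pipeline should
recover; their defaults are set to the magnitudes a trial of this kind
reports.
"""

from __future__ import annotations

import hashlib
import json
from pydantic import BaseModel, Field, field_validator, model_validator

WHEAT_MAIZE_YEAR = ["winter_wheat", "summer_maize"]


class RotationSpec(BaseModel):
    """One rotation system and the ground-truth effects it generates."""

    id: str
    crops_by_year: list[list[str]]
    n2o_n_annual_kg_ha: float = Field(ge=0, description="mean annual cumulative N2O-N, kg N/ha/yr")
    ch4_annual_kg_ha: float = Field(description="mean annual cumulative CH4 (negative = sink), kg/ha/yr")
    soc_accrual_t_c_ha_yr: float = Field(description="soil C accrual rate over the trial, t C/ha/yr")
    shannon_shift: float = Field(default=0.0, description="relative increase in true Shannon H, start to end")
    indicator_effect: float = Field(default=0.0, ge=0, description="soil indicator response, multiples of the per-indicator response step")
    carryover_boost: float = Field(default=0.0, ge=0, description="relative yield boost of wheat-maize years after a non-cereal year")

    @property
    def cycle_years(self) -> int:
        return len(self.crops_by_year)

    @field_validator("crops_by_year")
    @classmethod
    def _nonempty(cls, v: list[list[str]]) -> list[list[str]]:
        if not v:
            raise ValueError("crops_by_year must define at least one year")
        return v


class FluxModel(BaseModel):
    """Shape, noise, and chamber physics of the synthetic flux streams."""

    pulse_amplitude_ratio: float = Field(default=8.0, ge=0, description="N2O pulse peak as a multiple of baseline flux")
    pulse_half_life_days: float = Field(default=5.0, gt=0)
    noise_sd_fraction: float = Field(default=0.15, ge=0, description="flux noise SD as a fraction of the mean flux")
    conc_noise_ppm: dict[str, float] = Field(default={"N2O": 0.0005, "CH4": 0.002})
    ambient_ppm: dict[str, float] = Field(default={"N2O": 0.33, "CH4": 1.9})
    closure_minutes: list[float] = Field(default=[0.0, 12.0, 24.0, 36.0])
    chamber_height_m: float = Field(default=0.3, gt=0)
    pressure_kpa: float = Field(default=101.325, gt=0)
    temp_mean_k: float = Field(default=287.0, gt=0)
    temp_amplitude_k: float = Field(default=12.0, ge=0)
    sampling_interval_days: int = Field(default=7, ge=1)
    post_event_lag_days: int = Field(default=3, ge=1)

    @field_validator("conc_noise_ppm")
    @classmethod
    def _nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        if any(x < 0 for x in v.values()):
            raise ValueError("conc_noise_ppm values must be nonnegative")
        return v


class IndicatorSpec(BaseModel):
    """Baseline distribution and rotation response of one soil indicator."""

    mean: float
    sd: float = Field(gt=0)
    response: float = Field(description="change per unit indicator_effect (sign encodes direction)")


class SoilModel(BaseModel):
    """Layered SOC profile and topsoil indicator generator."""

    layers_cm: list[tuple[float, float]] = Field(
        default=[(0, 10), (10, 20), (20, 30), (30, 50), (50, 70), (70, 90)]
    )
    baseline_soc_g_kg: list[float] = Field(default=[11.5, 10.8, 6.79, 2.71, 2.47, 1.62])
    baseline_bd_g_cm3: list[float] = Field(default=[1.49, 1.52, 1.55, 1.58, 1.60, 1.62])
    accrual_depth_shares: list[float] = Field(default=[0.27, 0.24, 0.16, 0.13, 0.11, 0.09])
    plot_sd_g_kg: float = Field(default=0.25, ge=0, description="between-plot SD of layer SOC concentration")
    measurement_sd_g_kg: float = Field(default=0.1, ge=0, description="per-measurement SD of layer SOC concentration")
    bd_sd_g_cm3: float = Field(default=0.03, ge=0)
    indicators: dict[str, IndicatorSpec] = Field(
        default={
            "BD": IndicatorSpec(mean=1.49, sd=0.05, response=-0.04),
            "SWC": IndicatorSpec(mean=0.24, sd=0.02, response=0.01),
            "pH": IndicatorSpec(mean=7.6, sd=0.15, response=-0.06),
            "TN": IndicatorSpec(mean=1.06, sd=0.10, response=0.05),
            "SOC": IndicatorSpec(mean=11.5, sd=0.40, response=0.45),
            "DOC": IndicatorSpec(mean=120.0, sd=14.0, response=14.0),
            "NO3N": IndicatorSpec(mean=20.0, sd=3.5, response=1.6),
            "AP": IndicatorSpec(mean=9.3, sd=1.4, response=0.5),
            "MBC": IndicatorSpec(mean=220.0, sd=28.0, response=26.0),
            "MBN": IndicatorSpec(mean=35.0, sd=5.5, response=4.2),
        }
    )

    @model_validator(mode="after")
    def _lengths(self) -> "SoilModel":
        n = len(self.layers_cm)
        for name in ("baseline_soc_g_kg", "baseline_bd_g_cm3", "accrual_depth_shares"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one value per soil layer")
        if abs(sum(self.accrual_depth_shares) - 1.0) > 1e-9:
            raise ValueError("accrual_depth_shares must sum to 1")
        prev = self.layers_cm[0][0]
        for top, bottom in self.layers_cm:
            if bottom <= top or top != prev:
                raise ValueError("layers_cm must be contiguous, ordered, increasing")
            prev = bottom
        return self


class CropSpec(BaseModel):
    """Commercial yield distribution, prices, and composition of one crop."""

    yield_mean_kg_ha: float = Field(gt=0)
    yield_cv: float = Field(default=0.06, ge=0)
    price_yuan_kg: float = Field(gt=0)
    cost_yuan_ha: float = Field(ge=0)
    protein_fraction: float = Field(ge=0, le=1)
    moisture_fraction: float = Field(default=0.13, ge=0, lt=1)
    nutrients: dict[str, float] = Field(default={})


class EconomicModel(BaseModel):
    crops: dict[str, CropSpec]
    cpi: dict[int, float]
    cpi_base_year: int = 2008
    wheat_crop: str = "winter_wheat"

    @model_validator(mode="after")
    def _check(self) -> "EconomicModel":
        if any(v <= 0 for v in self.cpi.values()):
            raise ValueError("cpi values must be positive")
        if self.cpi_base_year not in self.cpi:
            raise ValueError(f"cpi must include the base year {self.cpi_base_year}")
        if self.wheat_crop not in self.crops:
            raise ValueError(f"wheat_crop {self.wheat_crop!r} missing from crops")
        return self


class MarkerSpec(BaseModel):
    """Log-normal community model for one gene marker's OTU tables."""

    n_taxa: int = Field(default=400, ge=2)
    lognormal_sigma: float = Field(default=2.2, gt=0)
    depth_mean: int = Field(default=15000, ge=10)
    depth_cv: float = Field(default=0.08, ge=0)


class OTUModel(BaseModel):
    markers: dict[str, MarkerSpec] = Field(
        default={
            "16S": MarkerSpec(n_taxa=400, lognormal_sigma=2.2, depth_mean=15000),
            "ITS": MarkerSpec(n_taxa=200, lognormal_sigma=2.8, depth_mean=12000),
        }
    )


def _default_rotations() -> list[RotationSpec]:
    return [
        RotationSpec(
            id="WM",
            crops_by_year=[WHEAT_MAIZE_YEAR],
            n2o_n_annual_kg_ha=8.9,
            ch4_annual_kg_ha=-2.004,
            soc_accrual_t_c_ha_yr=0.693,
            shannon_shift=0.0,
            indicator_effect=0.0,
        ),
        RotationSpec(
            id="SpWM",
            crops_by_year=[["sweet_potato"], WHEAT_MAIZE_YEAR],
            n2o_n_annual_kg_ha=4.54,
            ch4_annual_kg_ha=-3.53,
            soc_accrual_t_c_ha_yr=1.44,
            shannon_shift=0.085,
            indicator_effect=1.2,
            carryover_boost=0.29,
        ),
        RotationSpec(
            id="PWM",
            crops_by_year=[["peanut"], WHEAT_MAIZE_YEAR],
            n2o_n_annual_kg_ha=6.23,
            ch4_annual_kg_ha=-2.93,
            soc_accrual_t_c_ha_yr=2.03,
            shannon_shift=0.09,
            indicator_effect=1.8,
            carryover_boost=0.29,
        ),
        RotationSpec(
            id="SWM",
            crops_by_year=[["soybean"], WHEAT_MAIZE_YEAR],
            n2o_n_annual_kg_ha=5.16,
            ch4_annual_kg_ha=-3.05,
            soc_accrual_t_c_ha_yr=1.91,
            shannon_shift=0.08,
            indicator_effect=1.6,
            carryover_boost=0.27,
        ),
        RotationSpec(
            id="SmWM",
            crops_by_year=[["spring_maize"], WHEAT_MAIZE_YEAR],
            n2o_n_annual_kg_ha=7.60,
            ch4_annual_kg_ha=-2.67,
            soc_accrual_t_c_ha_yr=0.45,
            shannon_shift=0.0,
            indicator_effect=0.3,
        ),
        RotationSpec(
            id="RSWM",
            crops_by_year=[["ryegrass", "sorghum"], WHEAT_MAIZE_YEAR],
            n2o_n_annual_kg_ha=7.30,
            ch4_annual_kg_ha=-2.80,
            soc_accrual_t_c_ha_yr=0.21,
            shannon_shift=0.0,
            indicator_effect=0.15,
        ),
    ]


def _default_crops() -> dict[str, CropSpec]:
    protein = "crude_protein"
    return {
        "winter_wheat": CropSpec(
            yield_mean_kg_ha=6900, price_yuan_kg=2.6, cost_yuan_ha=7200,
            protein_fraction=0.13, moisture_fraction=0.13,
            nutrients={protein: 0.13, "fat": 0.020, "starch": 0.65, "fiber": 0.026, "calcium": 3.4e-4, "iron": 3.5e-5},
        ),
        "summer_maize": CropSpec(
            yield_mean_kg_ha=7400, price_yuan_kg=2.2, cost_yuan_ha=6500,
            protein_fraction=0.09, moisture_fraction=0.13,
            nutrients={protein: 0.09, "fat": 0.038, "starch": 0.70, "fiber": 0.029, "calcium": 1.0e-4, "iron": 2.4e-5},
        ),
        "spring_maize": CropSpec(
            yield_mean_kg_ha=8200, price_yuan_kg=2.2, cost_yuan_ha=6800,
            protein_fraction=0.09, moisture_fraction=0.13,
            nutrients={protein: 0.09, "fat": 0.038, "starch": 0.70, "fiber": 0.029, "calcium": 1.0e-4, "iron": 2.4e-5},
        ),
        "soybean": CropSpec(
            yield_mean_kg_ha=3100, price_yuan_kg=5.6, cost_yuan_ha=5200,
            protein_fraction=0.36, moisture_fraction=0.13,
            nutrients={protein: 0.36, "fat": 0.16, "starch": 0.19, "fiber": 0.10, "calcium": 1.9e-3, "iron": 8.2e-5},
        ),
        "peanut": CropSpec(
            yield_mean_kg_ha=4200, price_yuan_kg=7.0, cost_yuan_ha=9000,
            protein_fraction=0.25, moisture_fraction=0.14,
            nutrients={protein: 0.25, "fat": 0.44, "starch": 0.13, "fiber": 0.055, "calcium": 7.2e-4, "iron": 3.5e-5},
        ),
        "sweet_potato": CropSpec(
            yield_mean_kg_ha=37500, price_yuan_kg=1.35, cost_yuan_ha=14000,
            protein_fraction=0.015, moisture_fraction=0.70,
            nutrients={protein: 0.015, "fat": 0.002, "starch": 0.20, "fiber": 0.016, "calcium": 2.3e-4, "iron": 5.0e-6},
        ),
        "ryegrass": CropSpec(
            yield_mean_kg_ha=4500, price_yuan_kg=0.8, cost_yuan_ha=2200,
            protein_fraction=0.16, moisture_fraction=0.0,
            nutrients={protein: 0.16, "fat": 0.030, "starch": 0.12, "fiber": 0.24, "calcium": 5.5e-3, "iron": 1.0e-4},
        ),
        "sorghum": CropSpec(
            yield_mean_kg_ha=45000, price_yuan_kg=0.45, cost_yuan_ha=5500,
            protein_fraction=0.025, moisture_fraction=0.30,
            nutrients={protein: 0.025, "fat": 0.009, "starch": 0.17, "fiber": 0.075, "calcium": 1.2e-3, "iron": 4.0e-5},
        ),
    }


#: life-cycle emission factors, kg CO2-eq per native input unit
DEFAULT_EMISSION_FACTORS: dict[str, float] = {
    "n_fertilizer_kg": 8.3,
    "p2o5_fertilizer_kg": 1.51,
    "k2o_fertilizer_kg": 0.98,
    "diesel_l": 3.32,
    "electricity_kwh": 0.92,
    "pesticide_kg": 18.0,
    "seed_kg": 1.05,
    "labor_h": 0.0,
}


def _default_inventories() -> dict[str, dict[str, float]]:
    """Annualized input amounts per rotation (native units per ha per year)."""
    return {
        "WM": {"n_fertilizer_kg": 565, "p2o5_fertilizer_kg": 130, "k2o_fertilizer_kg": 120,
               "diesel_l": 180, "electricity_kwh": 3200, "pesticide_kg": 9, "seed_kg": 90, "labor_h": 120},
        "SpWM": {"n_fertilizer_kg": 330, "p2o5_fertilizer_kg": 110, "k2o_fertilizer_kg": 140,
                 "diesel_l": 150, "electricity_kwh": 2100, "pesticide_kg": 8, "seed_kg": 120, "labor_h": 160},
        "PWM": {"n_fertilizer_kg": 330, "p2o5_fertilizer_kg": 120, "k2o_fertilizer_kg": 130,
                "diesel_l": 150, "electricity_kwh": 1900, "pesticide_kg": 7, "seed_kg": 100, "labor_h": 150},
        "SWM": {"n_fertilizer_kg": 335, "p2o5_fertilizer_kg": 115, "k2o_fertilizer_kg": 125,
                "diesel_l": 150, "electricity_kwh": 1850, "pesticide_kg": 7, "seed_kg": 95, "labor_h": 130},
        "SmWM": {"n_fertilizer_kg": 400, "p2o5_fertilizer_kg": 120, "k2o_fertilizer_kg": 110,
                 "diesel_l": 160, "electricity_kwh": 1600, "pesticide_kg": 8, "seed_kg": 85, "labor_h": 110},
        "RSWM": {"n_fertilizer_kg": 520, "p2o5_fertilizer_kg": 140, "k2o_fertilizer_kg": 150,
                 "diesel_l": 200, "electricity_kwh": 2900, "pesticide_kg": 9, "seed_kg": 110, "labor_h": 170},
    }


class ExperimentConfig(BaseModel):
    """Full configuration of the synthetic rotation experiment."""

    rotations: list[RotationSpec] = Field(default_factory=_default_rotations)
    n_replicates: int = Field(default=3, ge=2)
    n_years: int = Field(default=6, ge=1)
    start_year: int = Field(default=2016)
    seed: int = Field(default=0, ge=0)
    flux: FluxModel = Field(default_factory=FluxModel)
    soil: SoilModel = Field(default_factory=SoilModel)
    econ: EconomicModel = Field(
        default_factory=lambda: EconomicModel(
            crops=_default_crops(),
            cpi={
                2008: 100.0, 2016: 117.2, 2017: 119.1, 2018: 121.6, 2019: 125.1,
                2020: 128.1, 2021: 129.4, 2022: 132.0,
            },
        )
    )
    otu: OTUModel = Field(default_factory=OTUModel)
    emission_factors: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_EMISSION_FACTORS)
    )
    inventories: dict[str, dict[str, float]] = Field(default_factory=_default_inventories)

    @model_validator(mode="after")
    def _validate(self) -> "ExperimentConfig":
        ids = [r.id for r in self.rotations]
        if len(set(ids)) != len(ids):
            raise ValueError("rotation ids must be unique")
        for rot in self.rotations:
            if rot.cycle_years > self.n_years:
                raise ValueError(
                    f"rotations[{rot.id}].crops_by_year: cycle of {rot.cycle_years} years "
                    f"exceeds n_years={self.n_years}"
                )
            for year_crops in rot.crops_by_year:
                for crop in year_crops:
                    if crop not in self.econ.crops:
                        raise ValueError(f"rotations[{rot.id}]: crop {crop!r} missing from econ.crops")
        if any(v < 0 for v in self.emission_factors.values()):
            raise ValueError("emission_factors must be nonnegative")
        for rot_id, inv in self.inventories.items():
            if rot_id not in ids:
                raise ValueError(f"inventories: unknown rotation {rot_id!r}")
            for kind, amount in inv.items():
                if amount < 0:
                    raise ValueError(f"inventories[{rot_id}][{kind}] must be nonnegative")
                if kind not in self.emission_factors:
                    raise ValueError(f"inventories[{rot_id}]: no emission factor for {kind!r}")
        missing_inv = set(ids) - set(self.inventories)
        if missing_inv:
            raise ValueError(f"inventories missing for rotations: {sorted(missing_inv)}")
        years = range(self.start_year, self.start_year + self.n_years)
        missing_cpi = [y for y in years if y not in self.econ.cpi]
        if missing_cpi:
            raise ValueError(f"econ.cpi missing years {missing_cpi}")
        return self

    def rotation(self, rot_id: str) -> RotationSpec:
        for rot in self.rotations:
            if rot.id == rot_id:
                return rot
        raise KeyError(f"unknown rotation {rot_id!r}")

    def config_hash(self) -> str:
        """Stable SHA-256 over the canonical JSON dump of the config."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def default_config(seed: int = 0) -> ExperimentConfig:
    """The six-rotation, three-replicate, six-year default design."""
    return ExperimentConfig(seed=seed)
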