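import pytest

from rotation_impact.config import (
    CropSpec,
    EconomicModel,
    ExperimentConfig,
    FluxModel,
    MarkerSpec,
    OTUModel,
    RotationSpec,
)
from rotation_impact.pipeline import run_pipeline
from rotation_impact.synthetic import generate_dataset

CPI = {2008: 100.0, 2016: 117.2, 2017: 119.1, 2018: 121.6, 2019: 125.1,
       2020: 128.1, 2021: 129.4, 2022: 132.0}


def tiny_config(
    seed: int = 0,
    rotations: list[RotationSpec] | None = None,
    inventories: dict | None = None,
    n_years: int = 2,
    n_replicates: int = 2,
    **kwargs,
) -> ExperimentConfig:
    """A deliberately small two-rotation experiment for fast Monte-Carlo loops."""
    if rotations is None:
        rotations = [
            RotationSpec(
                id="A", crops_by_year=[["winter_wheat", "summer_maize"]],
                n2o_n_annual_kg_ha=8.9, ch4_annual_kg_ha=-2.0,
                soc_accrual_t_c_ha_yr=2.0, shannon_shift=0.08, indicator_effect=1.5,
            ),
            RotationSpec(
                id="B", crops_by_year=[["soybean"]],
                n2o_n_annual_kg_ha=4.0, ch4_annual_kg_ha=-3.0,
                soc_accrual_t_c_ha_yr=0.5, shannon_shift=0.0, indicator_effect=0.0,
            ),
        ]
    if inventories is None:
        inventories = {
            r.id: {"n_fertilizer_kg": 300.0, "electricity_kwh": 1500.0} for r in rotations
        }
    defaults = dict(
        rotations=rotations,
        inventories=inventories,
        n_years=n_years,
        n_replicates=n_replicates,
        seed=seed,
        flux=FluxModel(sampling_interval_days=30),
        otu=OTUModel(markers={"16S": MarkerSpec(n_taxa=60, lognormal_sigma=1.5, depth_mean=2000)}),
        econ=EconomicModel(
            crops={
                "winter_wheat": CropSpec(yield_mean_kg_ha=6900, price_yuan_kg=2.6,
                                         cost_yuan_ha=7200, protein_fraction=0.13,
                                         nutrients={"crude_protein": 0.13}),
                "summer_maize": CropSpec(yield_mean_kg_ha=7400, price_yuan_kg=2.2,
                                         cost_yuan_ha=6500, protein_fraction=0.09,
                                         nutrients={"crude_protein": 0.09}),
                "soybean": CropSpec(yield_mean_kg_ha=3100, price_yuan_kg=5.6,
                                    cost_yuan_ha=5200, protein_fraction=0.36,
                                    nutrients={"crude_protein": 0.36}),
            },
            cpi=CPI,
        ),
    )
    defaults.update(kwargs)
    return ExperimentConfig(**defaults)


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline run on the six-rotation default design (shared across tests)."""
    return run_pipeline(config=ExperimentConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(tiny_config(seed=11))
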