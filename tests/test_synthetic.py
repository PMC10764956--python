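import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from rotation_impact import carbon_budget as cb
from rotation_impact.config import ExperimentConfig, FluxModel, RotationSpec
from rotation_impact.ghg_flux import fit_flux_table
from rotation_impact.synthetic import (
    ManagementCalendar,
    generate_dataset,
    generate_flux_series,
    shannon_of_lognormal_profile,
    sigma_for_shift,
)

from conftest import tiny_config


class TestDesign:
    def test_default_design_has_18_plots(self):
        ds = generate_dataset(ExperimentConfig(seed=0))
        assert len(ds.plots) == 18
        assert ds.plots["rotation"].nunique() == 6
        assert ds.plots["block"].nunique() == 3

    def test_randomized_complete_block_balance(self, small_dataset):
        plots = small_dataset.plots
        # every block holds every rotation exactly once
        counts = plots.groupby(["block", "rotation"]).size()
        assert (counts == 1).all()
        per_rotation = plots.groupby("rotation").size()
        assert (per_rotation == small_dataset.config.n_replicates).all()
        assert plots["plot"].is_unique

    def test_same_seed_identical_datasets(self):
        cfg = tiny_config(seed=5)
        ds1, ds2 = generate_dataset(cfg), generate_dataset(cfg)
        pd.testing.assert_frame_equal(ds1.chamber, ds2.chamber)
        pd.testing.assert_frame_equal(ds1.crop_records, ds2.crop_records)
        pd.testing.assert_frame_equal(ds1.soil_profiles, ds2.soil_profiles)
        for key in ds1.otu_tables:
            pd.testing.assert_frame_equal(ds1.otu_tables[key], ds2.otu_tables[key])

    def test_different_seed_differs(self):
        ds1 = generate_dataset(tiny_config(seed=1))
        ds2 = generate_dataset(tiny_config(seed=2))
        assert not ds1.chamber["conc_ppm"].equals(ds2.chamber["conc_ppm"])

    def test_roundtrip_through_directory(self, small_dataset, tmp_path):
        small_dataset.to_dir(tmp_path / "ds")
        from rotation_impact.synthetic import RotationDataset

        back = RotationDataset.from_dir(tmp_path / "ds")
        assert back.config.config_hash() == small_dataset.config.config_hash()
        pd.testing.assert_frame_equal(back.plots, small_dataset.plots)
        for key in small_dataset.otu_tables:
            pd.testing.assert_frame_equal(
                back.otu_tables[key], small_dataset.otu_tables[key], check_dtype=False
            )


class TestConfigValidation:
    def test_cycle_longer_than_trial_named(self):
        with pytest.raises(ValidationError, match="crops_by_year"):
            tiny_config(n_years=2, rotations=[
                RotationSpec(id="A", crops_by_year=[["winter_wheat"]] * 3,
                             n2o_n_annual_kg_ha=1, ch4_annual_kg_ha=-1,
                             soc_accrual_t_c_ha_yr=0.1),
            ], inventories={"A": {}})

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValidationError, match="noise_sd_fraction"):
            FluxModel(noise_sd_fraction=-0.1)

    def test_unknown_crop_rejected(self):
        with pytest.raises(ValidationError, match="missing from econ.crops"):
            tiny_config(rotations=[
                RotationSpec(id="A", crops_by_year=[["durum"]], n2o_n_annual_kg_ha=1,
                             ch4_annual_kg_ha=-1, soc_accrual_t_c_ha_yr=0.1),
            ], inventories={"A": {}})

    def test_inventory_without_factor_rejected(self):
        with pytest.raises(ValidationError, match="emission factor"):
            tiny_config(inventories={"A": {"unobtainium_kg": 1.0}, "B": {}})


class TestFluxGeneration:
    def test_null_model_gives_zero_slopes(self):
        model = FluxModel(conc_noise_ppm={"N2O": 0.0, "CH4": 0.0})
        cal = ManagementCalendar(fertilization_days=(10, 100))
        chamber, truth = generate_flux_series(
            "p", 0, cal, "N2O", model, 0.0, 0.0, 0.0, np.random.default_rng(0)
        )
        fits = fit_flux_table(chamber)
        assert np.allclose(fits["slope_ppm_min"], 0.0)
        assert np.allclose(truth["true_flux_kg_ha_h"], 0.0)

    def test_pulse_peaks_in_post_fertilization_window(self):
        model = FluxModel(conc_noise_ppm={"N2O": 0.0, "CH4": 0.0})
        cal = ManagementCalendar(fertilization_days=(100,))
        chamber, _ = generate_flux_series(
            "p", 0, cal, "N2O", model, 1e-5, 1e-4, 0.0, np.random.default_rng(0)
        )
        fits = fit_flux_table(chamber)
        peak_day = fits.loc[fits["flux_ug_m2_h"].idxmax(), "day"]
        assert 100 <= peak_day <= 103

    def test_ch4_slopes_negative_on_average(self, small_dataset):
        fits = fit_flux_table(small_dataset.chamber[small_dataset.chamber.gas == "CH4"])
        assert fits["flux_ug_m2_h"].mean() < 0

    def test_sampling_days_strictly_increasing(self, small_dataset):
        for plot, grp in small_dataset.chamber.groupby("plot"):
            days = np.sort(grp["day"].unique())
            assert np.all(np.diff(days) > 0)

    def test_empty_calendar_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            ManagementCalendar(fertilization_days=())


class TestOTUGeneration:
    def test_counts_nonnegative_integers(self, small_dataset):
        for table in small_dataset.otu_tables.values():
            values = table.to_numpy()
            assert np.issubdtype(values.dtype, np.integer)
            assert (values >= 0).all()

    def test_sigma_for_shift_raises_quantile_shannon(self):
        sigma = 2.0
        shifted = sigma_for_shift(sigma, 200, 0.08)
        assert shifted < sigma
        h0 = shannon_of_lognormal_profile(sigma, 200)
        h1 = shannon_of_lognormal_profile(shifted, 200)
        assert h1 == pytest.approx(1.08 * h0, rel=1e-6)

    def test_unreachable_shift_rejected(self):
        with pytest.raises(ValueError, match="Shannon"):
            sigma_for_shift(0.1, 50, 5.0)

    def test_ground_truth_tracks_true_shannon(self, small_dataset):
        truth = small_dataset.ground_truth["true_shannon"]
        assert {"marker", "timepoint", "plot", "true_shannon"} <= set(truth.columns)
        assert (truth["true_shannon"] > 0).all()


class TestParameterRecovery:
    def test_soc_accrual_recovered_across_seeds(self):
        # rotations configured at 2.0 vs 0.5 t C/ha/yr; the profile-based
        # delta-SOC estimator must recover both within Monte-Carlo error
        estimates = {"A": [], "B": []}
        n_seeds = 50
        for seed in range(n_seeds):
            cfg = tiny_config(seed=seed)
            ds = generate_dataset(cfg)
            for (plot,), grp in ds.soil_profiles.groupby(["plot"]):
                tps = sorted(grp["timepoint"].unique())
                s1 = cb.soc_stock(cb.SoilProfile.from_frame(grp[grp.timepoint == tps[0]]))
                s2 = cb.soc_stock(cb.SoilProfile.from_frame(grp[grp.timepoint == tps[-1]]))
                rate = cb.delta_soc(s1, s2, cfg.n_years).rate_t_c_ha_yr
                estimates[grp["rotation"].iloc[0]].append(rate)
        for rot, target in (("A", 2.0), ("B", 0.5)):
            values = np.asarray(estimates[rot])
            se = values.std(ddof=1) / np.sqrt(values.size)
            assert abs(values.mean() - target) < 3 * se + 1e-9
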