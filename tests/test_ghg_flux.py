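import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rotation_impact import ghg_flux as gf


def make_series(minutes, conc, gas="N2O", temp_k=298.15, pressure_kpa=101.325, height_m=0.3):
    return gf.ChamberSeries(
        plot="p1", day=0.0, gas=gas, minutes=np.array(minutes, float),
        conc_ppm=np.array(conc, float), temp_k=temp_k, pressure_kpa=pressure_kpa,
        height_m=height_m,
    )


class TestFitFlux:
    def test_constant_concentration_gives_zero_flux(self):
        fit = gf.fit_flux(make_series([0, 12, 24, 36], [0.33] * 4))
        assert fit.slope_ppm_min == 0.0
        assert fit.flux_ug_m2_h == 0.0

    def test_n2o_hand_example(self):
        # slope 0.001 ppm/min at 298.15 K, standard pressure, 0.3 m chamber
        fit = gf.fit_flux(make_series([0, 12, 24, 36], [0.320, 0.332, 0.344, 0.356]))
        assert fit.slope_ppm_min == pytest.approx(0.001, abs=1e-12)
        assert fit.flux_ug_m2_h == pytest.approx(32.37, abs=0.01)

    def test_ch4_uptake_gives_negative_flux(self):
        conc = 1.9 - 0.0005 * np.array([0, 12, 24, 36])
        fit = gf.fit_flux(make_series([0, 12, 24, 36], conc, gas="CH4"))
        assert fit.flux_ug_m2_h == pytest.approx(-5.89, abs=0.01)

    def test_doubling_chamber_height_doubles_flux(self):
        a = gf.fit_flux(make_series([0, 12, 24, 36], [0.32, 0.34, 0.36, 0.38], height_m=0.3))
        b = gf.fit_flux(make_series([0, 12, 24, 36], [0.32, 0.34, 0.36, 0.38], height_m=0.6))
        assert b.flux_ug_m2_h == pytest.approx(2 * a.flux_ug_m2_h)

    def test_standard_conditions_reduce_formula(self):
        # at T = T0 and P = P0 the flux is (M/V0) * H * slope * 60
        fit = gf.fit_flux(
            make_series([0, 12, 24, 36], [0.32, 0.332, 0.344, 0.356],
                        temp_k=gf.T_STANDARD, pressure_kpa=gf.P_STANDARD)
        )
        expected = 44.0 / 0.022414 * 0.3 * 0.001 * 60
        assert fit.flux_ug_m2_h == pytest.approx(expected, rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 time points"):
            make_series([0, 12], [0.3, 0.31])

    def test_r2_threshold_rejects_noisy_fit(self):
        with pytest.raises(ValueError, match="R\\^2"):
            gf.fit_flux(make_series([0, 12, 24, 36], [0.3, 0.4, 0.28, 0.41]), r2_min=0.9)

    def test_vectorized_table_matches_per_series_fit(self):
        rng = np.random.default_rng(5)
        rows = []
        for plot in ("p1", "p2"):
            for day in (0.0, 7.0):
                for gas in ("N2O", "CH4"):
                    conc = 0.4 + 0.002 * np.array([0, 12, 24, 36]) + rng.normal(0, 0.001, 4)
                    for t, c in zip([0, 12, 24, 36], conc):
                        rows.append(dict(plot=plot, day=day, gas=gas, t_min=t, conc_ppm=c,
                                         temp_k=290.0, pressure_kpa=101.0, height_m=0.3))
        table = pd.DataFrame(rows)
        fits = gf.fit_flux_table(table)
        for row in fits.itertuples():
            sub = table[
                (table["plot"] == row.plot) & (table["day"] == row.day) & (table["gas"] == row.gas)
            ]
            single = gf.fit_flux(make_series(sub.t_min, sub.conc_ppm, gas=row.gas,
                                             temp_k=290.0, pressure_kpa=101.0))
            assert row.flux_ug_m2_h == pytest.approx(single.flux_ug_m2_h, rel=1e-10)
            assert row.r_squared == pytest.approx(single.r_squared, rel=1e-8)


class TestCumulativeEmission:
    def test_constant_flux_rectangle(self):
        # 0.0001 kg/ha/h held for 7 days = 0.0001 * 7 * 24
        s = gf.FluxSeries("p", "N2O", days=[0, 7], flux_kg_ha_h=[1e-4, 1e-4])
        assert gf.cumulative_emission(s) == pytest.approx(0.0168)

    def test_trapezoid_hand_example(self):
        s = gf.FluxSeries("p", "N2O", days=[0, 1], flux_kg_ha_h=[0.0, 0.002])
        assert gf.cumulative_emission(s) == pytest.approx(0.024)

    def test_zero_fluxes_integrate_to_zero(self):
        s = gf.FluxSeries("p", "N2O", days=[0, 3, 9], flux_kg_ha_h=[0, 0, 0])
        assert gf.cumulative_emission(s) == 0.0

    def test_unordered_days_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            gf.FluxSeries("p", "N2O", days=[3, 1], flux_kg_ha_h=[0.1, 0.1])

    def test_single_point_rejected(self):
        s = gf.FluxSeries("p", "N2O", days=[1], flux_kg_ha_h=[0.1])
        with pytest.raises(ValueError, match="at least 2"):
            gf.cumulative_emission(s)

    def test_window_clips_with_interpolated_boundaries(self):
        s = gf.FluxSeries("p", "N2O", days=[0, 10], flux_kg_ha_h=[0.0, 0.001])
        # linear flux: integral over [0, 5] is a quarter of the full triangle
        full = gf.cumulative_emission(s)
        assert gf.cumulative_emission(s, window=(0, 5)) == pytest.approx(full / 4)

    def test_matches_fine_grid_integration_of_interpolant(self):
        rng = np.random.default_rng(42)
        days = np.sort(rng.uniform(0, 120, 40))
        days += np.arange(40) * 1e-6  # guard against ties
        flux = rng.normal(0, 1e-3, 40)
        s = gf.FluxSeries("p", "CH4", days=days, flux_kg_ha_h=flux)
        grid = np.union1d(np.linspace(days[0], days[-1], 400_001), days)
        fine = np.trapezoid(np.interp(grid, days, flux), grid) * 24.0
        assert gf.cumulative_emission(s) == pytest.approx(fine, rel=1e-10)


class TestGWP:
    def test_unit_n2o(self):
        assert gf.gwp(1.0, 0.0) == 273.0

    def test_unit_ch4(self):
        assert gf.gwp(0.0, 1.0) == 27.0

    def test_methane_sink_reduces_total(self):
        assert gf.gwp(1.0, -0.5) == 273.0 - 13.5

    @settings(deadline=None, derandomize=True)
    @given(
        a=st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
        b=st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
    )
    def test_linearity(self, a, b):
        total = gf.gwp(a[0] + b[0], a[1] + b[1])
        assert total == pytest.approx(gf.gwp(*a) + gf.gwp(*b), abs=1e-9)


class TestNitrogenBasis:
    def test_molar_identity(self):
        assert gf.n_basis_to_species(28.0) == pytest.approx(44.0)
        assert gf.n_basis_to_species(0.0) == 0.0

    def test_field_scale_value(self):
        assert gf.n_basis_to_species(8.9) == pytest.approx(13.986, abs=1e-3)

    def test_round_trip(self):
        assert gf.species_to_n_basis(gf.n_basis_to_species(3.7)) == pytest.approx(3.7)

    def test_negative_emission_rejected(self):
        with pytest.raises(ValueError):
            gf.n_basis_to_species(-1.0)
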