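import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coastalch4 import (
    ChamberSeries,
    GasExchangeEnv,
    SyntheticSiteSpec,
    chamber_flux,
    classify_redox,
    equilibrium_concentration,
    find_oxycline,
    gas_transfer_velocity,
    generate_chamber,
    generate_watercolumn,
    profile_from_arrays,
    schmidt_number,
    sea_air_flux,
)
from coastalch4.errors import NonLinearSeriesWarning
from coastalch4.watercolumn import average_chamber_fluxes, surface_concentration

from oracles import oracle_co_mmol_m3, oracle_k_m_d, oracle_schmidt_ch4, oracle_seaair_flux


class TestClassifyRedox:
    @pytest.mark.parametrize("o2,h2s,expected", [
        (100.0, 0.0, "oxic"),
        (63.0, 0.0, "oxic"),
        (20.0, 0.0, "hypoxic"),
        (62.9, 0.0, "hypoxic"),
        (0.0, 43.0, "euxinic"),
        (0.5, 5.0, "euxinic"),
    ])
    def test_threshold_classes(self, o2, h2s, expected):
        assert classify_redox(o2, h2s).label == expected

    def test_anoxic_without_sulfide_is_flagged(self):
        with pytest.warns(UserWarning):
            assert classify_redox(0.0, 0.0).label == "anoxic_non_euxinic"

    @settings(max_examples=200, deadline=None)
    @given(o2=st.floats(0, 400), h2s=st.floats(0, 400))
    def test_classification_is_total(self, o2, h2s):
        """Every (O2, sulfide) pair maps to exactly one class."""
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            label = classify_redox(o2, h2s).label
        assert label in {"oxic", "hypoxic", "euxinic", "anoxic_non_euxinic"}


class TestSchmidtNumber:
    def test_seawater_polynomial_value(self):
        assert schmidt_number(20.0, 35.0) == pytest.approx(
            oracle_schmidt_ch4(20.0, 35.0), rel=1e-12)

    def test_monotone_decrease_with_temperature(self):
        temps = np.linspace(0, 30, 31)
        sc = [schmidt_number(t, 4.5) for t in temps]
        assert np.all(np.diff(sc) < 0)
        np.testing.assert_allclose(sc, [oracle_schmidt_ch4(t, 4.5) for t in temps],
                                   rtol=1e-12)

    def test_mid_salinity_is_mean_of_endpoints(self):
        t = 12.0
        assert schmidt_number(t, 17.5) == pytest.approx(
            0.5 * (schmidt_number(t, 0.0) + schmidt_number(t, 35.0)))


class TestGasTransferVelocity:
    def test_zero_wind_zero_k(self):
        assert gas_transfer_velocity(0.0, 660.0) == 0.0

    def test_unit_conversion_of_coefficient(self):
        """u10=1, Sc=660: k = 0.251 cm/h = 0.06024 m/d."""
        assert gas_transfer_velocity(1.0, 660.0) == pytest.approx(0.06024)

    def test_matches_oracle_at_field_conditions(self):
        sc = schmidt_number(10.0, 4.5)
        assert gas_transfer_velocity(5.0, sc) == pytest.approx(
            oracle_k_m_d(5.0, sc), rel=1e-12)


class TestEquilibriumConcentration:
    def test_henry_linearity_in_mixing_ratio(self):
        c1 = equilibrium_concentration(10.0, 4.5, 1900.0)
        c2 = equilibrium_concentration(10.0, 4.5, 3800.0)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_matches_solubility_oracle(self):
        assert equilibrium_concentration(10.0, 4.5, 1900.0) == pytest.approx(
            oracle_co_mmol_m3(10.0, 4.5, 1900.0), rel=1e-12)
        # a few nmol/L at present-day atmospheric methane
        assert 0.002 < equilibrium_concentration(10.0, 4.5, 1900.0) < 0.006

    def test_monotone_decrease_with_temperature(self):
        temps = np.linspace(0, 30, 16)
        c = [equilibrium_concentration(t, 4.5, 1900.0) for t in temps]
        assert np.all(np.diff(c) < 0)


class TestSeaAirFlux:
    def test_equilibrium_means_zero_flux(self):
        c_o = equilibrium_concentration(10.0, 4.5, 1900.0)
        env = GasExchangeEnv(u10=5.0, temperature=10.0, salinity=4.5, C_W=c_o)
        assert sea_air_flux(env).F_atm == pytest.approx(0.0, abs=1e-15)

    def test_direct_product(self):
        env = GasExchangeEnv(u10=5.0, temperature=10.0, salinity=4.5, C_W=0.2)
        saf = sea_air_flux(env)
        assert saf.F_atm == pytest.approx(saf.k * (saf.C_W - saf.C_O), rel=1e-15)

    def test_full_chain_matches_composed_oracle(self):
        """u10=5, T=10, S=4.5, C_W=0.39 mmol/m3 against the oracle chain."""
        env = GasExchangeEnv(u10=5.0, temperature=10.0, salinity=4.5, C_W=0.39)
        assert sea_air_flux(env).F_atm == pytest.approx(
            oracle_seaair_flux(5.0, 10.0, 4.5, 0.39), rel=1e-12)


class TestChamberFlux:
    def _series(self, slope_ppb_s, noise=0.0, rng=None, area=0.1195):
        t = np.arange(31) * 10.0
        ppb = 1900.0 + slope_ppb_s * t
        if rng is not None and noise > 0:
            ppb = ppb + rng.normal(0, noise, t.size)
        return ChamberSeries(time_s=t, ch4_ppb=ppb, chamber_volume=0.0323,
                             chamber_area=area)

    def test_constant_concentration_zero_flux(self):
        assert chamber_flux(self._series(0.0)).flux == pytest.approx(0.0, abs=1e-12)

    def test_recovers_planted_flux_within_5pct(self, rng):
        spec = SyntheticSiteSpec(seed=3)
        f_true = 0.2
        series = generate_chamber(spec, f_true, noise_sd_ppb=0.01 * 60.0)
        mean, _ = average_chamber_fluxes([chamber_flux(s) for s in series])
        assert mean == pytest.approx(f_true, rel=0.05)

    def test_doubling_area_halves_flux(self):
        f1 = chamber_flux(self._series(0.2)).flux
        f2 = chamber_flux(self._series(0.2, area=2 * 0.1195)).flux
        assert f2 == pytest.approx(f1 / 2)

    def test_nonlinear_series_flagged(self, rng):
        series = self._series(0.01, noise=30.0, rng=rng)
        with pytest.warns(NonLinearSeriesWarning):
            result = chamber_flux(series)
        assert result.nonlinear


class TestFindOxycline:
    def test_interpolated_crossing(self):
        prof = profile_from_arrays([1.0, 10.0, 20.0], "watercolumn",
                                   o2=[300.0, 100.0, 1.0])
        expected = 10 + 10 * (100 - 63) / (100 - 1)
        assert find_oxycline(prof) == pytest.approx(expected)

    def test_fully_oxic_profile_returns_none(self):
        prof = profile_from_arrays([1.0, 10.0, 20.0], "watercolumn",
                                   o2=[300.0, 290.0, 280.0])
        assert find_oxycline(prof) is None

    def test_recovers_generated_oxycline(self):
        spec = SyntheticSiteSpec(seed=9, redox_true="euxinic",
                                 oxycline_depth_true=8.0, noise_cv=0.0,
                                 delta_noise=0.0)
        prof = generate_watercolumn(spec)
        assert find_oxycline(prof) == pytest.approx(8.0, abs=spec.wc_grid)


def test_surface_concentration_prefers_exact_1m_sample():
    prof = profile_from_arrays([1.0, 2.0], "watercolumn", ch4=[0.39, 0.5])
    assert surface_concentration(prof) == 0.39


def test_surface_concentration_nearest_within_2m_warns():
    prof = profile_from_arrays([1.8, 5.0], "watercolumn", ch4=[0.3, 0.6])
    with pytest.warns(UserWarning, match="nearest"):
        assert surface_concentration(prof) == 0.3


def test_chamber_and_gas_exchange_fluxes_agree():
    """Dual-method closure: chamber and calculated fluxes within 25% when a
    single true emission drives both."""
    from coastalch4.pipeline import run_synthetic_site
    spec = SyntheticSiteSpec(seed=21, redox_true="euxinic",
                             oxycline_depth_true=10.0, F_sed_true=4.0,
                             escape_true=0.3, smtz_depth_true=0.03)
    budget = run_synthetic_site(spec, with_chamber=True)
    assert budget.F_atm_insitu == pytest.approx(budget.F_atm_calc, rel=0.25)
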