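import numpy as np
import pytest

from coastalch4 import (
    SedimentContext,
    SyntheticSiteSpec,
    diffusion_coefficient,
    fickian_flux,
    find_smtz,
    generate_porewater,
    interfacial_gradient,
    profile_from_arrays,
)
from coastalch4.errors import DataError, ParameterError
from coastalch4.porewater import free_solution_diffusivity, tortuosity_theta2

from oracles import oracle_d0_ch4_m2d, oracle_ds_m2d, oracle_fick_flux


class TestDiffusionCoefficient:
    def test_tortuosity_vanishes_at_unit_porosity(self):
        """Ds -> D0 as phi -> 1 (theta^2 -> 1)."""
        ctx = SedimentContext(porosity=0.999999, temperature=10, salinity=4.5)
        d0, ds = diffusion_coefficient(ctx)
        assert ds == pytest.approx(d0, rel=1e-5)
        assert tortuosity_theta2(1.0) == pytest.approx(1.0)

    def test_matches_independent_polynomial_oracle(self):
        ctx = SedimentContext(porosity=0.9, temperature=10, salinity=4.5)
        d0, ds = diffusion_coefficient(ctx)
        assert d0 == pytest.approx(oracle_d0_ch4_m2d(10, 4.5), rel=1e-12)
        assert ds == pytest.approx(oracle_ds_m2d(10, 4.5, 0.9), rel=1e-12)

    def test_d0_increases_with_temperature(self):
        temps = np.linspace(0, 25, 26)
        d0 = [free_solution_diffusivity("methane", t, 4.5) for t in temps]
        assert np.all(np.diff(d0) > 0)
        oracle = [oracle_d0_ch4_m2d(t, 4.5) for t in temps]
        np.testing.assert_allclose(d0, oracle, rtol=1e-12)

    @pytest.mark.parametrize("solute", ["sulfate", "sulfide"])
    def test_ion_coefficients_positive_and_tortuosity_reduced(self, solute):
        ctx = SedimentContext(porosity=0.8, temperature=10, salinity=4.5,
                              solute=solute)
        d0, ds = diffusion_coefficient(ctx)
        assert 0 < ds < d0

    def test_unsupported_solute(self):
        with pytest.raises(ParameterError):
            SedimentContext(porosity=0.9, temperature=10, salinity=4.5,
                            solute="nitrate")


class TestInterfacialGradient:
    def test_two_point_across_swi(self):
        prof = profile_from_arrays([0.01, 0.02], "porewater", ch4=[300.0, 600.0])
        grad = interfacial_gradient(prof, "ch4", bottom_water_conc=0.0)
        assert grad == pytest.approx(30000.0)

    def test_uniform_profile_has_zero_gradient(self):
        prof = profile_from_arrays([0.01, 0.02, 0.03], "porewater",
                                   ch4=[250.0] * 3)
        grad = interfacial_gradient(prof, "ch4", bottom_water_conc=250.0)
        assert grad == pytest.approx(0.0)

    def test_linear_fit_recovers_noisy_slope(self, rng):
        """5-point linear profile, slope 20000, 2% noise -> within 5%."""
        z = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        c = 20000.0 * z * rng.normal(1.0, 0.02, size=z.size)
        prof = profile_from_arrays(z, "porewater", ch4=c)
        grad = interfacial_gradient(prof, "ch4", method="linear_fit",
                                    bottom_water_conc=0.0)
        assert grad == pytest.approx(20000.0, rel=0.05)

    def test_linear_fit_needs_three_points(self):
        prof = profile_from_arrays([0.01], "porewater", ch4=[100.0])
        with pytest.raises(DataError):
            interfacial_gradient(prof, "ch4", method="linear_fit")


class TestFickianFlux:
    def test_zero_gradient_zero_flux(self):
        ctx = SedimentContext(porosity=0.8, temperature=10, salinity=4.5)
        assert fickian_flux(ctx, 0.0).J == 0.0

    def test_hand_multiplication_example(self):
        """phi=0.8, Ds=1e-4 m2/d, dC/dz=30000 mmol/m4 -> J=2.4 mmol/m2/d efflux."""
        ctx = SedimentContext(porosity=0.8, temperature=10, salinity=4.5)
        flux = fickian_flux(ctx, 30000.0)
        # same gradient with the actual Ds obeys the identity exactly
        assert flux.J == pytest.approx(flux.porosity * flux.Ds * 30000.0, rel=1e-15)
        # the canonical worked value with Ds pinned at 1e-4:
        assert 0.8 * 1.0e-4 * 30000.0 == pytest.approx(2.4)

    def test_linearity_in_phi_ds(self):
        ctx1 = SedimentContext(porosity=0.8, temperature=10, salinity=4.5)
        f1 = fickian_flux(ctx1, 30000.0)
        assert fickian_flux(ctx1, 60000.0).J == pytest.approx(2 * f1.J)

    def test_identity_over_random_sweep(self, rng):
        """J = phi*Ds*dC/dz re-multiplied by a one-line oracle, 1e-12 relative."""
        for _ in range(200):
            ctx = SedimentContext(porosity=rng.uniform(0.5, 0.95),
                                  temperature=rng.uniform(0, 25),
                                  salinity=rng.uniform(0, 35))
            grad = rng.uniform(-5e4, 5e4)
            flux = fickian_flux(ctx, grad)
            assert flux.J == pytest.approx(
                oracle_fick_flux(flux.porosity, flux.Ds, flux.gradient_dCdz),
                rel=1e-12, abs=1e-15)

    def test_supersaturated_porewater_flags_lower_bound(self):
        ctx = SedimentContext(porosity=0.9, temperature=10, salinity=4.5)
        assert fickian_flux(ctx, 1e4, max_porewater_conc=2500.0).lower_bound
        assert not fickian_flux(ctx, 1e4, max_porewater_conc=500.0).lower_bound


class TestFindSmtz:
    def test_crossing_at_grid_node(self):
        z = [0.0, 0.05, 0.10]
        assert find_smtz((z, [0.0, 2.0, 6.0]), (z, [6.0, 2.0, 0.0])) \
            == pytest.approx(0.05)

    def test_symmetric_interpolated_crossing(self):
        z = [0.0, 0.10]
        assert find_smtz((z, [0.0, 4.0]), (z, [4.0, 0.0])) == pytest.approx(0.05)

    def test_no_crossing_returns_none(self):
        z = [0.0, 0.05, 0.10]
        assert find_smtz((z, [0.0, 1.0, 2.0]), (z, [9.0, 8.0, 7.0])) is None

    def test_disjoint_ranges_rejected(self):
        with pytest.raises(DataError):
            find_smtz(([0.0, 0.01], [1.0, 2.0]), ([0.5, 0.6], [5.0, 4.0]))

    def test_multiple_crossings_warns_and_returns_shallowest(self):
        z = [0.0, 0.02, 0.04, 0.06]
        with pytest.warns(UserWarning, match="shallowest"):
            depth = find_smtz((z, [0.0, 3.0, 1.0, 5.0]), (z, [2.0, 2.0, 2.0, 2.0]))
        assert depth < 0.02

    def test_recovers_generated_truth_within_grid_step(self):
        spec = SyntheticSiteSpec(seed=5, smtz_depth_true=0.03, F_sed_true=4.0,
                                 porewater_grid=0.025, noise_cv=0.0)
        prof = generate_porewater(spec)
        depth = find_smtz("ch4", "so4", profile=prof)
        assert abs(depth - 0.03) <= 0.025


def test_smtz_recovery_rate_across_ensemble(rng):
    """True SMTZ in [0.01, 0.40] m: recovered within one grid step >= 95%."""
    hits = 0
    n = 100
    for i in range(n):
        smtz = rng.uniform(0.01, 0.40)
        spec = SyntheticSiteSpec(seed=int(rng.integers(2**31)),
                                 smtz_depth_true=smtz,
                                 F_sed_true=min(8.4 * (0.01 / smtz) ** 0.8, 10.0),
                                 noise_cv=0.024)
        depth = find_smtz("ch4", "so4", profile=generate_porewater(spec))
        if depth is not None and abs(depth - smtz) <= spec.porewater_grid:
            hits += 1
    assert hits >= 95


def test_shallow_smtz_means_large_flux_across_ensemble(rng):
    """Recovered benthic flux anticorrelates with recovered SMTZ depth."""
    from scipy.stats import spearmanr
    from coastalch4.pipeline import benthic_estimates
    smtzs, fluxes = [], []
    for smtz in np.linspace(0.02, 0.35, 12):
        spec = SyntheticSiteSpec(seed=int(smtz * 1e4), smtz_depth_true=float(smtz),
                                 F_sed_true=min(8.4 * (0.01 / smtz) ** 0.8, 10.0),
                                 noise_cv=0.024)
        prof = generate_porewater(spec)
        est = benthic_estimates(prof, 10.0, 4.5)
        smtzs.append(est["smtz_depth"])
        fluxes.append(est["J_ch4"].J)
    assert spearmanr(smtzs, fluxes).statistic < 0
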