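"""Demographic models, expected spectra, composite likelihood and fitting."""

import numpy as np
import pytest

from whalepop.demography import (
    EpochModel,
    ScalingContext,
    TwoPopModel,
    composite_loglik,
    effective_migrants,
    expected_sfs_epoch,
    expected_sfs_epoch_mc,
    expected_sfs_structured_mc,
    fit_model,
    fin_whale_enp_3epoch,
    grid_search,
    likelihood_ratio_test,
    parametric_bootstrap_ci,
    physical_to_scaled,
    scale_parameters,
)
from whalepop.sfs import FoldedSFS

CTX = ScalingContext(mu=1e-8, L=1e7)


class TestExpectedSfs:
    def test_theta_identity_n2(self):
        m = EpochModel.one_epoch(1000)
        full = expected_sfs_epoch(m, 2, CTX, fold=False)
        assert full[1] == pytest.approx(4 * 1000 * CTX.mu * CTX.L)

    def test_one_over_i_law(self):
        m = EpochModel.one_epoch(2000)
        full = expected_sfs_epoch(m, 6, CTX, fold=False)
        np.testing.assert_allclose(full[1:6], full[1] / np.arange(1, 6), rtol=1e-9)

    def test_degenerate_size_change_equals_constant(self):
        m1 = EpochModel.one_epoch(750)
        m2 = EpochModel.two_epoch(750, 750, 400)
        np.testing.assert_allclose(
            expected_sfs_epoch(m1, 12, CTX, fold=False),
            expected_sfs_epoch(m2, 12, CTX, fold=False),
            rtol=1e-9,
        )

    def test_linear_scaling_in_mu_and_L(self):
        m = EpochModel.three_epoch(500, 900, 100, 600, 30)
        a = expected_sfs_epoch(m, 8, ScalingContext(mu=1e-8, L=1e6), fold=False)
        b = expected_sfs_epoch(m, 8, ScalingContext(mu=2e-8, L=3e6), fold=False)
        np.testing.assert_allclose(b[1:8], 6 * a[1:8], rtol=1e-9)

    def test_masses_non_negative(self):
        m = EpochModel.four_epoch(800, 200, 1500, 50, 500, 200, 10)
        sfs = expected_sfs_epoch(m, 20, CTX)
        assert (sfs.counts >= 0).all()

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            EpochModel.two_epoch(1000, -5, 100)

    def test_analytic_matches_monte_carlo(self):
        # oracle equivalence on a bottlenecked history
        m = EpochModel.three_epoch(1000, 2000, 120, 700, 60)
        ana = expected_sfs_epoch(m, 10, CTX, fold=False)
        mc, se = expected_sfs_epoch_mc(m, 10, CTX, n_trees=8000, seed=9, fold=False)
        z = (ana[1:10] - mc[1:10]) / se[1:10]
        assert np.abs(z).max() < 3.5


class TestStructuredMC:
    def test_symmetric_model_symmetric_joint(self):
        m = TwoPopModel(n_anc=500, n1=500, n2=500, t_split=300,
                        m_1_to_2=1e-3, m_2_to_1=1e-3)
        joint, se = expected_sfs_structured_mc(m, 6, 6, CTX, n_trees=3000, seed=2)
        diff = joint.counts - joint.counts.T
        scale = np.sqrt(se**2 + se.T**2) + 1e-12
        inner = (slice(1, -1),) * 2
        assert np.abs(diff[inner] / scale[inner]).max() < 4.0

    def test_single_deme_matches_analytic(self):
        # equal sizes across the split: history is constant-size overall
        m = TwoPopModel(n_anc=600, n1=600, n2=50, t_split=500.0)
        joint, se = expected_sfs_structured_mc(m, 8, 0, CTX, n_trees=6000, seed=4)
        ana = expected_sfs_epoch(EpochModel.one_epoch(600), 8, CTX, fold=False)
        marg = joint.counts[:, 0]
        z = (marg[1:8] - ana[1:8]) / (se[1:8, 0] + 1e-12)
        assert np.abs(z).max() < 3.5

    def test_no_migration_old_split_empty_off_marginals(self):
        m = TwoPopModel(n_anc=500, n1=400, n2=400, t_split=2e5)
        joint, se = expected_sfs_structured_mc(m, 4, 4, CTX, n_trees=2000, seed=6)
        shared = joint.counts[1:-1, 1:-1]
        assert shared.sum() < 1e-3 * joint.counts[1:, :].sum()


class TestCompositeLoglik:
    def test_maximised_at_truth(self):
        p = np.array([0.0, 0.4, 0.3, 0.2, 0.1])
        obs = 100 * p
        ll_true = composite_loglik(obs, p)
        ll_off = composite_loglik(obs, np.array([0.0, 0.1, 0.2, 0.3, 0.4]))
        assert ll_true > ll_off
        assert ll_true == pytest.approx(100 * np.sum(p[1:] * np.log(p[1:] / p[1:].sum())))

    def test_two_cell_hand_value(self):
        # obs (3,1) vs equal expectation: 4 log(1/2)
        ll = composite_loglik(np.array([0, 3, 1]), np.array([0, 0.5, 0.5]))
        assert ll == pytest.approx(4 * np.log(0.5), abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        obs = rng.integers(1, 50, size=7).astype(float)
        exp = rng.random(7) + 0.1
        perm = np.concatenate([[0], rng.permutation(np.arange(1, 7))])
        assert composite_loglik(obs, exp) == pytest.approx(
            composite_loglik(obs[perm], exp[perm])
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_loglik(np.ones(4), np.ones(5))


class TestFitting:
    def test_recovers_constant_size(self):
        truth = EpochModel.one_epoch(5000)
        ctx = ScalingContext(mu=1e-8, L=1e8)
        exp = expected_sfs_epoch(truth, 12, ctx)
        fit = fit_model(exp, "1Epoch")
        scale_parameters(fit, ctx)
        assert fit.physical["N_ANC"] == pytest.approx(5000, rel=1e-6)

    def test_recovers_two_epoch_from_expected_sfs(self):
        truth = EpochModel.two_epoch(4000, 800, 2000)
        ctx = ScalingContext(mu=1e-8, L=1e8)
        exp = expected_sfs_epoch(truth, 16, ctx)
        fit = fit_model(exp, "2Epoch", n_restarts=10, seed=1)
        scale_parameters(fit, ctx)
        assert fit.physical["N_ANC"] == pytest.approx(4000, rel=0.05)
        assert fit.physical["N_CUR"] == pytest.approx(800, rel=0.15)

    def test_collapsed_bounds_return_point(self):
        truth = EpochModel.two_epoch(1000, 500, 400)
        exp = expected_sfs_epoch(truth, 8, CTX)
        scaled = physical_to_scaled(truth)
        fit = fit_model(exp, "2Epoch", fixed=scaled)
        assert fit.params["nu"] == pytest.approx(scaled["nu"])
        assert np.isfinite(fit.log_likelihood)


class TestScaling:
    def test_theta_to_n_anc(self):
        ctx = ScalingContext(mu=1.0, L=1.0, generation_time=1.0)
        assert ctx.n_anc_from_theta(4.0) == pytest.approx(1.0)

    def test_printed_epoch_size_ratio(self):
        # relative size 1.451 at N_ANC=16,479 gives the printed 23,913
        assert 1.4511196 * 16479 == pytest.approx(23913, abs=1.0)

    def test_two_generations_in_years(self):
        ctx = ScalingContext()
        assert 2 * ctx.generation_time == pytest.approx(51.8)

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(ValueError):
            ScalingContext().n_anc_from_theta(0.0)


class TestLRT:
    def test_equal_likelihoods(self):
        a = _fake_fit(-50.0)
        stat, p = likelihood_ratio_test(a, _fake_fit(-50.0), df=1)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_hand_value(self):
        stat, p = likelihood_ratio_test(_fake_fit(-100.0), _fake_fit(-95.0), df=1)
        assert stat == pytest.approx(10.0)
        assert p == pytest.approx(0.001565, abs=2e-6)

    def test_floor_at_zero(self):
        stat, p = likelihood_ratio_test(_fake_fit(-90.0), _fake_fit(-95.0), df=2)
        assert stat == 0.0

    def test_shift_invariance(self):
        s1, _ = likelihood_ratio_test(_fake_fit(-100.0), _fake_fit(-95.0), df=1)
        s2, _ = likelihood_ratio_test(_fake_fit(-400.0), _fake_fit(-395.0), df=1)
        assert s1 == pytest.approx(s2)


def _fake_fit(ll):
    from whalepop.demography.fit import FitResult

    return FitResult(model="2Epoch", params={}, log_likelihood=ll)


class TestBootstrap:
    def test_zero_noise_collapses_ci(self):
        truth = EpochModel.two_epoch(2000, 400, 1500)
        ctx = ScalingContext(mu=1e-8, L=5e8)
        exp = expected_sfs_epoch(truth, 10, ctx)
        fit = fit_model(exp, "2Epoch", n_restarts=8, seed=0)
        # very large L: multinomial noise is negligible relative to signal
        out = parametric_bootstrap_ci(fit, exp, n_boot=5, seed=1, n_restarts=4,
                                      engine="none")
        lo, hi = out.ci["nu"]
        assert hi - lo < 0.2 * fit.params["nu"]

    def test_lower_bound_truncated_at_zero(self):
        from whalepop.demography.fit import FitResult

        fit = FitResult(model="2Epoch", params={"nu": 0.01, "T": 0.5},
                        log_likelihood=-1.0)
        truth = EpochModel.two_epoch(1000, 10, 500)
        exp = expected_sfs_epoch(truth, 8, ScalingContext(mu=1e-8, L=1e6))
        out = parametric_bootstrap_ci(fit, exp, n_boot=6, seed=3, n_restarts=2)
        assert all(lo >= 0 for k, (lo, hi) in out.ci.items() if k != "n_boot_ok")


class TestGridSearch:
    def setup_method(self):
        self.truth = EpochModel.three_epoch(2000, 3000, 200, 1500, 40)
        ctx = ScalingContext(mu=1e-8, L=1e8)
        self.obs = expected_sfs_epoch(self.truth, 10, ctx)
        self.fit = fit_model(self.obs, "3Epoch", n_restarts=12, seed=2)

    def test_fitted_point_inside_region(self):
        nu = self.fit.params["nuF"]
        t = self.fit.params["TF"]
        ll, region = grid_search(self.obs, self.fit, [nu], [t])
        assert region[0, 0]

    def test_region_nests_with_threshold(self):
        nus = np.geomspace(0.01, 1.0, 6)
        ts = np.geomspace(1e-4, 0.05, 6)
        ll, r2 = grid_search(self.obs, self.fit, nus, ts, threshold=2.0)
        _, r5 = grid_search(self.obs, self.fit, nus, ts, threshold=5.0)
        assert (r2 <= r5).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(self.obs, self.fit, [], [1.0])


class TestEffectiveMigrants:
    def test_printed_goc_value(self):
        assert round(effective_migrants(3.42e-3, 114), 2) == 0.39

    def test_printed_enp_value(self):
        assert round(effective_migrants(9.24e-5, 17386), 2) == 1.61

    def test_zero_migration(self):
        assert effective_migrants(0.0, 1000) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            effective_migrants(1.5, 100)
        with pytest.raises(ValueError):
            effective_migrants(0.1, -3)


def test_printed_enp_model_catalogued():
    m = fin_whale_enp_3epoch()
    assert m.sizes == [16479, 23913, 305]
    assert m.change_times()[0] == 4424
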