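"""Full-conditional correctness: analytic forms, Monte-Carlo moments,
Metropolis oracle for the inverse-Gaussian latents, chain mechanics."""

import numpy as np
import pytest
from scipy import stats

import hvarnet as hv
from hvarnet.design import ConfigurationError
from hvarnet.gibbs import (StudyPrecomp, d_conditional_params,
                           gamma_conditional_params, lambda2_conditional_params,
                           tau_conditional_params)


def _single_roi_stack(Y, conditions=("only",), K=1):
    spec = hv.ModelSpec(R=1, K=K, conditions=conditions)
    W = np.ones((len(Y), 1))
    s = hv.SubjectSeries("a", "group1", np.asarray(Y, float)[:, None], W)
    return hv.build_study([s], spec), spec


def _study_stack(R=3, K=2, S=5, T=100, conditions=("rest", "active"), seed=0):
    """S single-session subjects of length T."""
    design = hv.BlockDesign(sessions=1, scans_per_session=T,
                            block_length=T // 4 if len(conditions) > 1 else T,
                            condition_order=conditions)
    truth = hv.make_default_truth(R=R, K=K, n_edges=1, seed=seed, design=design,
                                  conditions=conditions, subjects_per_group=S)
    study = hv.simulate_study(truth)
    return hv.build_study(study.series, truth.spec), truth


class TestPhiConditional:
    def test_scalar_conjugate_normal_by_hand(self):
        # one design row (1), response 2, tau=1, prior precision alpha+lam=1:
        # posterior mean 2/(1+1) = 1, variance 1/2
        stack, spec = _single_roi_stack([1.0, 2.0])
        state = hv.ModelState.initial(spec, 1)
        state.alpha[:] = 0.5
        state.lambda2 = 0.5
        rng = np.random.default_rng(0)
        draws = np.array([hv.sample_phi(rng, state, stack, hv.HyperParams())[0]
                          for _ in range(50000)])
        se_mean = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 1.0) < 3 * se_mean
        assert abs(draws.var() - 0.5) < 3 * 0.5 * np.sqrt(2.0 / draws.size)

    def test_no_data_limit_is_prior(self):
        # all-zero series: conditional reduces to N(0, V_tau V_Phi)
        stack, spec = _single_roi_stack(np.zeros(6))
        state = hv.ModelState.initial(spec, 1)
        state.tau[:] = 2.0
        state.alpha[:] = 1.5
        state.lambda2 = 0.5
        rng = np.random.default_rng(1)
        draws = np.array([hv.sample_phi(rng, state, stack, hv.HyperParams())[0]
                          for _ in range(40000)])
        var_expect = 1.0 / (2.0 * (1.5 + 0.5))
        assert abs(draws.mean()) < 3 * draws.std() / np.sqrt(draws.size)
        assert draws.var() == pytest.approx(var_expect, rel=0.05)

    def test_block_sampler_matches_global_matrix_formula(self):
        # empirical moments vs mu_phi, V computed from the dense stacked
        # matrices of the classical-linear-model form
        stack, truth = _study_stack(R=2, K=1, S=2, T=24, seed=3)
        spec = truth.spec
        rng = np.random.default_rng(2)
        state = hv.ModelState.initial(spec, stack.S)
        state.xi = rng.normal(0, 0.1, size=state.xi.shape)
        state.tau = np.array([1.3, 0.7])
        state.alpha = rng.uniform(0.5, 2.0, size=spec.q)
        state.lambda2 = 0.8
        X, Z, y = stack.X, stack.Z, stack.y
        pre = StudyPrecomp(stack)
        itau_diag = np.tile(state.tau, X.shape[0] // spec.R)  # row precisions
        prior_prec = pre.tau_h(state.tau) * (state.alpha + state.lambda2)
        A = X.T @ (itau_diag[:, None] * X) + np.diag(prior_prec)
        mu = np.linalg.solve(A, X.T @ (itau_diag * (y - Z @ state.xi.ravel())))
        V = np.linalg.inv(A)
        draws = np.array([hv.sample_phi(rng, state, stack, hv.HyperParams())
                          for _ in range(30000)])
        se = np.sqrt(np.diag(V) / draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - mu) < 4 * se)
        # atol covers MC noise ~ sqrt(Vii Vjj / n) on exact-zero entries
        assert np.allclose(np.cov(draws.T), V, rtol=0.1, atol=2e-3)


class TestXiConditional:
    def test_no_data_limit_is_prior(self):
        stack, spec = _single_roi_stack(np.zeros(6))
        state = hv.ModelState.initial(spec, 1)
        state.d[:] = 4.0
        rng = np.random.default_rng(3)
        draws = np.array([hv.sample_xi(rng, state, stack, hv.HyperParams())[0, 0]
                          for _ in range(40000)])
        assert draws.var() == pytest.approx(0.25, rel=0.05)

    def test_huge_precision_shrinks_deviations_to_zero(self, tiny_stack):
        spec = tiny_stack.spec
        state = hv.ModelState.initial(spec, tiny_stack.S)
        state.d[:] = 1e12
        rng = np.random.default_rng(4)
        xi = hv.sample_xi(rng, state, tiny_stack, hv.HyperParams())
        assert np.max(np.abs(xi)) < 1e-3

    def test_matches_global_matrix_formula(self):
        stack, truth = _study_stack(R=2, K=1, S=2, T=24, seed=5)
        spec = truth.spec
        rng = np.random.default_rng(5)
        state = hv.ModelState.initial(spec, stack.S)
        state.phi = rng.normal(0, 0.2, size=spec.q)
        state.tau = np.array([0.9, 1.4])
        state.d = rng.uniform(2.0, 5.0, size=(1, spec.q))
        X, Z, y = stack.X, stack.Z, stack.y
        itau_diag = np.tile(state.tau, X.shape[0] // spec.R)
        Dstar_inv = np.tile(state.d[0], stack.S)
        A = Z.T @ (itau_diag[:, None] * Z) + np.diag(Dstar_inv)
        mu = np.linalg.solve(A, Z.T @ (itau_diag * (y - X @ state.phi)))
        draws = np.array([hv.sample_xi(rng, state, stack, hv.HyperParams()).ravel()
                          for _ in range(30000)])
        V = np.linalg.inv(A)
        se = np.sqrt(np.diag(V) / draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - mu) < 4 * se)


class TestAlphaConditional:
    def test_draws_strictly_positive(self, tiny_stack):
        spec = tiny_stack.spec
        state = hv.ModelState.initial(spec, tiny_stack.S)
        state.phi = np.random.default_rng(6).normal(size=spec.q)
        a = hv.sample_alpha(np.random.default_rng(7), state, tiny_stack,
                            hv.HyperParams())
        assert np.all(a > 0)

    def test_matches_metropolis_oracle(self):
        # target density alpha^{-3/2} exp(-(tau phi^2 alpha + gamma/alpha)/2)
        stack, spec = _single_roi_stack([1.0, 2.0, 1.5])
        state = hv.ModelState.initial(spec, 1)
        state.phi = np.array([0.6])
        state.tau = np.array([1.7])
        state.gamma = 2.3
        rng = np.random.default_rng(8)
        n = 20000
        draws = np.array([hv.sample_alpha(rng, state, stack, hv.HyperParams())[0]
                          for _ in range(n)])

        def logpost(a):
            return (-1.5 * np.log(a)
                    - 0.5 * (state.tau[0] * state.phi[0] ** 2 * a
                             + state.gamma / a))

        x = 1.0
        chain = np.empty(n)
        lp = logpost(x)
        for i in range(5 * n):
            prop = x * np.exp(0.8 * rng.normal())
            lp_prop = logpost(prop)
            # log-scale random walk: Jacobian term log(prop/x)
            if np.log(rng.random()) < lp_prop - lp + np.log(prop / x):
                x, lp = prop, lp_prop
            if i % 5 == 4:
                chain[i // 5] = x
        ks = stats.ks_2samp(draws, chain[n // 5:])
        assert ks.pvalue > 0.01

    def test_large_phi_gives_stochastically_smaller_alpha(self):
        stack, spec = _single_roi_stack([1.0, 2.0, 1.5])
        rng = np.random.default_rng(9)
        means = []
        for mag in (0.1, 5.0):
            state = hv.ModelState.initial(spec, 1)
            state.phi = np.array([mag])
            means.append(np.mean([
                hv.sample_alpha(rng, state, stack, hv.HyperParams())[0]
                for _ in range(4000)]))
        assert means[1] < means[0]


class TestTauConditional:
    def test_printed_shape_formula(self):
        # (T-K)S + CRK + 2 r_tau over 2: ((100-2)*5 + 2*3*2 + 2)/2 = 252
        stack, truth = _study_stack(R=3, K=2, S=5, T=100)
        state = hv.ModelState.initial(truth.spec, stack.S)
        shape, rate = tau_conditional_params(state, stack,
                                             hv.HyperParams(r_tau=1.0))
        assert np.allclose(shape, 252.0)

    def test_zero_residuals_zero_phi_rate_is_h_tau(self):
        stack, spec = _single_roi_stack(np.zeros(8))
        state = hv.ModelState.initial(spec, 1)
        shape, rate = tau_conditional_params(state, stack,
                                             hv.HyperParams(h_tau=0.37))
        assert rate[0] == pytest.approx(0.37)

    def test_concentrates_near_true_precision_with_much_data(self):
        design = hv.BlockDesign(sessions=1, scans_per_session=4000,
                                block_length=1000)
        truth = hv.make_default_truth(R=2, K=1, n_edges=0, seed=10,
                                      design=design, deviation_sd=0.0,
                                      noise_var=0.5, subjects_per_group=1)
        study = hv.simulate_study(truth)
        stack = hv.build_study(study.series, truth.spec)
        state = hv.ModelState.initial(truth.spec, 1)
        state.phi = truth.coefficients.flatten()
        shape, rate = tau_conditional_params(state, stack, hv.HyperParams())
        post_mean = shape / rate
        assert np.allclose(post_mean, 2.0, rtol=0.1)  # true precision 1/0.5

    def test_moments_match_gamma_form(self, tiny_stack):
        spec = tiny_stack.spec
        rng = np.random.default_rng(11)
        state = hv.ModelState.initial(spec, tiny_stack.S)
        state.phi = rng.normal(0, 0.3, size=spec.q)
        shape, rate = tau_conditional_params(state, tiny_stack, hv.HyperParams())
        draws = np.array([hv.sample_tau(rng, state, tiny_stack, hv.HyperParams())
                          for _ in range(20000)])
        for r in range(spec.R):
            se = np.sqrt(shape[r]) / rate[r] / np.sqrt(draws.shape[0])
            assert abs(draws[:, r].mean() - shape[r] / rate[r]) < 3 * se


class TestScalarHyperConditionals:
    def _state_stack(self):
        stack, truth = _study_stack(R=5, K=2, S=2, T=40, seed=12)
        state = hv.ModelState.initial(truth.spec, stack.S)
        return state, stack, truth.spec

    def test_lambda2_printed_shape_51(self):
        state, stack, spec = self._state_stack()
        assert spec.q == 100
        shape, _ = lambda2_conditional_params(
            state, stack, hv.HyperParams(r_lambda=1.0), variant="printed")
        assert shape == pytest.approx(51.0)

    def test_lambda2_joint_shape_is_prior_shape(self):
        state, stack, _ = self._state_stack()
        shape, _ = lambda2_conditional_params(
            state, stack, hv.HyperParams(r_lambda=1.0), variant="joint")
        assert shape == pytest.approx(1.0)

    def test_lambda2_rate_reduces_to_h_lambda_at_zero_phi(self):
        state, stack, _ = self._state_stack()
        state.phi[:] = 0.0
        for variant in ("joint", "printed"):
            _, rate = lambda2_conditional_params(
                state, stack, hv.HyperParams(h_lambda=0.21), variant=variant)
            assert rate == pytest.approx(0.21)

    def test_gamma_shape_r_plus_q(self):
        state, stack, spec = self._state_stack()
        shape, _ = gamma_conditional_params(state, stack,
                                            hv.HyperParams(r_gamma=2.0))
        assert shape == pytest.approx(2.0 + spec.q)

    def test_gamma_rate_limit_large_alpha(self):
        state, stack, _ = self._state_stack()
        state.alpha[:] = 1e12
        _, rate = gamma_conditional_params(state, stack,
                                           hv.HyperParams(h_gamma=0.13))
        assert rate == pytest.approx(0.13, abs=1e-6)

    def test_gamma_moment_identity(self):
        state, stack, _ = self._state_stack()
        rng = np.random.default_rng(13)
        state.alpha = rng.uniform(0.5, 3.0, size=state.alpha.size)
        shape, rate = gamma_conditional_params(state, stack, hv.HyperParams())
        draws = np.array([hv.sample_gamma_hyper(rng, state, stack, hv.HyperParams())
                          for _ in range(10000)])
        se = np.sqrt(shape) / rate / np.sqrt(draws.size)
        assert abs(draws.mean() - shape / rate) < 3 * se


class TestDConditional:
    def _ten_subject_stack(self):
        design = hv.BlockDesign(sessions=1, scans_per_session=24, block_length=12)
        truth = hv.make_default_truth(R=2, K=1, n_edges=0, seed=14,
                                      design=design, subjects_per_group=10)
        study = hv.simulate_study(truth)
        return hv.build_study(study.series, truth.spec), truth.spec

    def test_printed_shape_s10_rd1(self):
        stack, spec = self._ten_subject_stack()
        state = hv.ModelState.initial(spec, 10)
        shape, _ = d_conditional_params(state, stack, hv.HyperParams(r_d=1.0),
                                        variant="printed")
        assert np.allclose(shape, 6.0)  # S (r_d - 1/2) + 1

    def test_joint_shape_s10_rd1(self):
        stack, spec = self._ten_subject_stack()
        state = hv.ModelState.initial(spec, 10)
        shape, _ = d_conditional_params(state, stack, hv.HyperParams(r_d=1.0),
                                        variant="joint")
        assert np.allclose(shape, 6.0)  # r_d + S/2 coincides at r_d = 1

    def test_zero_deviations_rates(self):
        stack, spec = self._ten_subject_stack()
        state = hv.ModelState.initial(spec, 10)
        hyper = hv.HyperParams(h_d=0.05)
        _, rate_printed = d_conditional_params(state, stack, hyper, "printed")
        _, rate_joint = d_conditional_params(state, stack, hyper, "joint")
        assert np.allclose(rate_printed, 10 * 0.05)
        assert np.allclose(rate_joint, 0.05)

    def test_rd_below_half_rejected(self):
        with pytest.raises(ConfigurationError):
            hv.HyperParams(r_d=0.4)

    def test_recovers_known_deviation_variance(self):
        # xi fixed at draws with variance v: posterior mean of 1/d near v
        stack, spec = self._ten_subject_stack()
        rng = np.random.default_rng(15)
        state = hv.ModelState.initial(spec, 10)
        v = 0.04
        state.xi = rng.normal(0, np.sqrt(v), size=(10, spec.q))
        shape, rate = d_conditional_params(state, stack, hv.HyperParams(h_d=1e-4))
        var_mean = rate / (shape - 1.0)  # E[1/d] for Gamma(shape, rate)
        assert np.median(var_mean) == pytest.approx(v, rel=0.5)


class TestChainMechanics:
    def test_retained_draw_count_formula(self):
        cfg = hv.SamplerConfig(iterations=80000, burn_in=60000, thin=5, seed=0)
        assert cfg.n_retained == 4000

    def test_same_seed_gives_identical_chains(self, tiny_stack):
        cfg = hv.SamplerConfig(iterations=120, burn_in=40, thin=2, seed=77)
        a = hv.run_gibbs(tiny_stack, config=cfg)
        b = hv.run_gibbs(tiny_stack, config=cfg)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.tau, b.tau)
        assert np.array_equal(a.lambda2, b.lambda2)

    def test_smoke_run_small_model(self):
        design = hv.BlockDesign(sessions=1, scans_per_session=40, block_length=10)
        truth = hv.make_default_truth(R=2, K=1, n_edges=1, seed=16,
                                      design=design, subjects_per_group=2)
        study = hv.simulate_study(truth)
        stack = hv.build_study(study.series, truth.spec)
        post = hv.run_gibbs(stack, config=hv.SamplerConfig(
            iterations=400, burn_in=100, thin=3, seed=1))
        assert post.n_draws == 100
        assert np.all(post.tau > 0) and np.all(post.d > 0)
        assert np.all(post.alpha > 0)


class TestGeweke:
    def test_null_calibration_iid_chains(self):
        rng = np.random.default_rng(17)
        z = np.array([hv.geweke_diagnostic(rng.standard_normal(1000))
                      for _ in range(200)])
        assert np.mean(np.abs(z) < 4) >= 0.99

    def test_mean_step_change_detected(self):
        x = np.concatenate([np.zeros(500), np.ones(500)])
        x += np.random.default_rng(18).normal(0, 0.1, size=1000)
        assert abs(hv.geweke_diagnostic(x)) > 10

    def test_affine_invariance(self):
        x = np.random.default_rng(19).standard_normal(800)
        z1 = hv.geweke_diagnostic(x)
        z2 = hv.geweke_diagnostic(5.0 * x - 3.0)
        assert z1 == pytest.approx(z2, abs=1e-12)

    def test_constant_chain_flagged_not_crashed(self):
        z = hv.geweke_diagnostic(np.ones(500))
        assert np.isnan(z)
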