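"""Graded-response probabilities, marginal likelihood, EM fit, fit indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

import caremirt as cm
from caremirt.mgrm import (
    EstimationOptions,
    QuadratureSpec,
    ScaleStructure,
    _category_prob_grid,
    compare_structures,
)


def _toy_params(rho=0.3):
    return cm.MGRMParameters(
        np.array([[1.0, 0.0], [0.0, 1.5]]),
        np.array([[1.0, 0.0, -1.0, -2.0], [2.0, 1.0, 0.0, -1.0]]),
        np.array([[1.0, rho], [rho, 1.0]]),
    )


class TestCategoryProbabilities:
    def test_cumulative_is_half_when_linear_predictor_zero(self):
        p = cm.MGRMParameters(
            np.array([[1.0, 0.5]]), np.array([[0.0, -1e-9, -2e-9, -3e-9]]), np.eye(2)
        )
        # a.theta + d ~ 0 for all boundaries
        out = cm.cumulative_prob(p, np.array([0.0, 0.0]), 0)
        assert np.allclose(out, 0.5, atol=1e-9)

    def test_unloaded_factor_is_ignored(self):
        p = cm.MGRMParameters(
            np.array([[2.0, 0.0]]), np.array([[-2.0, -2.1, -2.2, -2.3]]), np.eye(2)
        )
        # theta = (1, -7): only the loaded coordinate matters, a.theta + d_2 = 0
        out = cm.cumulative_prob(p, np.array([1.0, -7.0]), 0)
        assert out[0] == pytest.approx(0.5, abs=1e-12)

    def test_cumulative_known_values(self):
        p = cm.MGRMParameters(
            np.array([[1.2, 0.0]]), np.array([[2.0, 1.0, 0.0, -1.0]]), np.eye(2)
        )
        out = cm.cumulative_prob(p, np.array([0.5, 0.0]), 0)
        assert np.allclose(out, [0.9309, 0.8320, 0.6457, 0.4013], atol=5e-5)

    def test_category_probs_are_first_differences(self):
        p = cm.MGRMParameters(
            np.array([[1.2, 0.0]]), np.array([[2.0, 1.0, 0.0, -1.0]]), np.eye(2)
        )
        out = cm.category_prob(p, np.array([0.5, 0.0]), 0)
        # reference values are differences of 4-decimal roundings
        assert np.allclose(out, [0.0691, 0.0989, 0.1863, 0.2444, 0.4013], atol=1e-4)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unknown_item_raises(self):
        p = _toy_params()
        with pytest.raises(KeyError):
            cm.cumulative_prob(p, np.zeros(2), 7)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_probability_invariants_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        a = np.zeros((1, 2))
        a[0, rng.integers(2)] = rng.uniform(0.3, 3.0)
        d = np.sort(rng.normal(scale=2.0, size=4))[::-1]
        d += np.array([3e-6, 2e-6, 1e-6, 0.0])  # break exact ties
        p = cm.MGRMParameters(a, d[None, :], np.eye(2))
        theta = rng.normal(size=2)
        pstar = cm.cumulative_prob(p, theta, 0)
        probs = cm.category_prob(p, theta, 0)
        assert (np.diff(pstar) < 0).all()
        assert (probs >= 0).all()
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_compensatory_monotonicity(self):
        p = _toy_params()
        lo = cm.cumulative_prob(p, np.array([-0.5, 0.0]), 0)
        hi = cm.cumulative_prob(p, np.array([0.5, 0.0]), 0)
        assert (hi > lo).all()


class TestMarginalLoglik:
    def test_zero_slope_item_is_quadrature_free(self):
        p = cm.MGRMParameters(
            np.array([[0.0, 0.0]]), np.array([[1.0, 0.0, -1.0, -2.0]]), np.eye(2)
        )
        data = cm.ItemResponseMatrix(np.array([[3]]))
        expected = np.log(cm.category_prob(p, np.zeros(2), 0)[2])
        for nodes in (11, 21, 41):
            assert cm.marginal_loglik(p, data, nodes) == pytest.approx(expected, abs=1e-10)

    def test_matches_dense_grid_oracle(self):
        toy = _toy_params()
        data = cm.ItemResponseMatrix(np.array([[1, 2], [3, 4], [5, 5]]))
        ll = cm.marginal_loglik(toy, data, QuadratureSpec(41))
        # brute-force rectangle rule over [-6, 6]^2 at step 0.01
        step = 0.01
        axis = np.arange(-6, 6 + step / 2, step)
        g1, g2 = np.meshgrid(axis, axis, indexing="ij")
        grid = np.column_stack([g1.ravel(), g2.ravel()])
        dens = stats.multivariate_normal([0, 0], toy.latent_cov).pdf(grid) * step**2
        P = _category_prob_grid(toy.a, toy.d, grid)
        oracle = 0.0
        for row in data.values:
            lik = np.ones(len(grid))
            for i, x in enumerate(row):
                lik *= P[i, :, x - 1]
            oracle += np.log((lik * dens).sum())
        assert ll == pytest.approx(oracle, abs=1e-4)

    def test_quadrature_convergence(self):
        toy = _toy_params()
        data = cm.ItemResponseMatrix(np.array([[2, 3], [4, 2]]))
        ll21 = cm.marginal_loglik(toy, data, 21)
        ll41 = cm.marginal_loglik(toy, data, 41)
        assert abs(ll41 - ll21) < 1e-6

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            cm.marginal_loglik(_toy_params(), cm.ItemResponseMatrix(np.array([[1, 1]])), 5)


class TestFitIndices:
    def test_zero_case(self):
        f = cm.fit_indices(0.0, 0, 10)
        assert f.aic == 0 and f.bic == 0 and f.sabic == 0

    def test_closed_forms(self):
        f = cm.fit_indices(-100.0, 10, 382)
        assert f.aic == pytest.approx(220.0)
        assert f.bic == pytest.approx(200 + 10 * np.log(382))
        assert f.sabic == pytest.approx(200 + 10 * np.log(384 / 24))
        assert f.sabic < f.bic  # ln(384/24) < ln(382)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            cm.fit_indices(-1.0, 2, 0)


class TestLikelihoodRatioTest:
    def test_equal_logliks(self):
        stat, p = cm.likelihood_ratio_test(-50.0, -50.0, 1)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_chi_square_quantile(self):
        stat, p = cm.likelihood_ratio_test(-100.0, -100.0 + 3.84 / 2, 1)
        assert p == pytest.approx(0.0500, abs=5e-4)

    def test_p_matches_numerical_chi2_integration(self):
        stat, p = cm.likelihood_ratio_test(-80.0, -75.0, 3)
        from scipy.integrate import quad

        dens = lambda x: stats.chi2.pdf(x, 3)
        tail, _ = quad(dens, stat, np.inf)
        assert p == pytest.approx(tail, abs=1e-6)

    def test_reversed_nesting_rejected(self):
        with pytest.raises(ValueError):
            cm.likelihood_ratio_test(-10.0, -20.0, 1)


class TestEMFit:
    def test_loglik_monotone_and_invariants(self, fitted_model):
        data, params, ability, indices = fitted_model
        trace = np.array(params.loglik_trace)
        assert (np.diff(trace) >= -1e-8).all()
        assert (np.diff(params.d, axis=1) < 0).all()
        assert np.isfinite(ability.theta).all() and (ability.se > 0).all()
        assert indices.n_obs == data.n_persons

    def test_empty_category_raises_with_item_name(self, true_params):
        values = np.clip(
            cm.sample_responses(true_params, cm.sample_thetas(200, 0.5, 0), 1).values,
            1, 5,
        )
        values[:, 3] = 2  # constant column
        with pytest.raises(ValueError, match="item04"):
            cm.fit(cm.ItemResponseMatrix(values), true_params.structure)

    def test_unidimensional_reduction_matches_direct_mml(self):
        """Degenerate one-factor structure agrees with an independent direct fit."""
        rng = np.random.default_rng(10)
        structure = ScaleStructure.between_item([0, 0, 0], n_factors=1)
        a = np.array([[1.5], [1.0], [2.0]])
        d = np.array([[1.2, 0.2, -0.8, -1.8]] * 3) + rng.normal(scale=0.1, size=(3, 1))
        d.sort(axis=1)
        d = d[:, ::-1].copy()
        truth = cm.MGRMParameters(a, d, np.eye(1), structure)
        thetas = rng.standard_normal((800, 1))
        data = cm.sample_responses(truth, thetas, 11)
        est, _, _ = cm.fit(data, structure)

        # independent oracle: direct joint ML on a dense 1-D grid
        axis = np.arange(-6, 6.01, 0.05)
        dens = stats.norm.pdf(axis) * 0.05
        counts = np.stack(
            [np.eye(5)[data.values[:, i] - 1] for i in range(3)], axis=0
        )  # (I, n, K)

        def unpack(v):
            av = v[:3]
            dv = v[3:].reshape(3, 4)
            dv = -np.sort(-dv, axis=1)
            return av, dv

        def nll(v):
            av, dv = unpack(v)
            z = axis[None, :, None] * av[:, None, None] + dv[:, None, :]
            c = special.expit(z)
            pad = np.concatenate(
                [np.ones((3, len(axis), 1)), c, np.zeros((3, len(axis), 1))], axis=2
            )
            P = np.clip(pad[:, :, :-1] - pad[:, :, 1:], 1e-12, 1)
            # person likelihood on the grid
            ll = np.zeros((data.n_persons, len(axis)))
            for i in range(3):
                ll += np.log(P[i])[None, :, :].transpose(0, 1, 2)[
                    0, :, data.values[:, i] - 1
                ]
            return -np.log(np.exp(ll) @ dens).sum()

        from scipy.optimize import minimize

        v0 = np.concatenate([np.ones(3), np.tile([1.5, 0.5, -0.5, -1.5], 3)])
        res = minimize(nll, v0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-5, "fatol": 1e-7})
        a_or, d_or = unpack(res.x)
        assert np.abs(est.a[:, 0] - a_or).max() < 0.05
        assert np.abs(est.d - d_or).max() < 0.05


class TestScoreEAP:
    def test_symmetric_responses_give_zero_theta(self):
        p = cm.MGRMParameters(
            np.array([[1.5, 0.0], [0.0, 1.5]]),
            np.array([[1.5, 0.5, -0.5, -1.5]] * 2),
            np.eye(2),
        )
        est = cm.score_eap(p, np.array([[3, 3]]))
        assert np.allclose(est.theta, 0.0, atol=1e-8)

    def test_extreme_responses_are_ordered(self, true_params):
        lo = cm.score_eap(true_params, np.full((1, 10), 1))
        hi = cm.score_eap(true_params, np.full((1, 10), 5))
        assert (hi.theta > lo.theta).all()

    def test_matches_dense_grid_posterior_mean(self):
        toy = _toy_params()
        resp = np.array([[2, 4]])
        est = cm.score_eap(toy, resp, quad=41)
        step = 0.02
        axis = np.arange(-6, 6 + step / 2, step)
        g1, g2 = np.meshgrid(axis, axis, indexing="ij")
        grid = np.column_stack([g1.ravel(), g2.ravel()])
        dens = stats.multivariate_normal([0, 0], toy.latent_cov).pdf(grid)
        P = _category_prob_grid(toy.a, toy.d, grid)
        lik = P[0, :, 1] * P[1, :, 3] * dens
        mean = (grid * lik[:, None]).sum(axis=0) / lik.sum()
        assert np.abs(est.theta[0] - mean).max() < 0.01


class TestStructureComparison:
    def test_negative_specific_slope_forces_between(self, monkeypatch):
        """The over-extraction rule overrides fit indices."""
        rng = np.random.default_rng(3)
        truth = cm.default_true_params()
        thetas = cm.sample_thetas(400, 0.5, 31)
        data = cm.sample_responses(truth, thetas, 32)

        import caremirt.mgrm as mgrm_mod

        real_fit = mgrm_mod.fit

        def doctored_fit(d, structure, options=None):
            params, ability, indices = real_fit(d, structure, options)
            if structure.model_kind == "bifactor":
                # inject a negative specific slope and a huge loglik advantage
                i = np.argmax(structure.loading_pattern[:, 1])
                params.a[i, 1] = -0.2
                indices = cm.fit_indices(indices.loglik + 500.0, indices.n_params, indices.n_obs)
            return params, ability, indices

        monkeypatch.setattr(mgrm_mod, "fit", doctored_fit)
        cmp = mgrm_mod.compare_structures(data, [0] * 5 + [1] * 5)
        assert cmp.lr_pvalue < 0.05
        assert cmp.negative_specific_slopes.any()
        assert cmp.recommended == "between"

    def test_identifiable_bifactor_truth_detected(self):
        s2 = ScaleStructure.bifactor([0] * 5 + [1] * 5)
        ag = np.array([1.8, 1.0, 1.4, 2.0, 0.9, 1.1, 1.9, 1.3, 0.8, 1.6])
        asp = np.array([0.6, 1.6, 1.0, 0.5, 1.5, 1.4, 0.6, 1.2, 1.6, 0.8])
        idx = np.arange(10)
        a = np.column_stack([ag, np.where(idx < 5, asp, 0.0), np.where(idx >= 5, asp, 0.0)])
        truth = cm.MGRMParameters(a, cm.default_true_params().d, np.eye(3), s2)
        rng = np.random.default_rng(5)
        th3 = rng.multivariate_normal(np.zeros(3), np.eye(3), size=800)
        data = cm.sample_responses(truth, th3, 33)
        cmp = compare_structures(data, [0] * 5 + [1] * 5)
        assert cmp.recommended == "bifactor"


class TestMCMCMode:
    def test_smoke_recovers_rough_structure(self, true_params):
        thetas = cm.sample_thetas(300, 0.5, 51)
        data = cm.sample_responses(true_params, thetas, 52)
        options = EstimationOptions(estimator="mcmc", mcmc_cycles=300, seed=7)
        params, ability, indices = cm.fit(data, true_params.structure, options)
        assert (np.diff(params.d, axis=1) < 0).all()
        assert np.isfinite(indices.loglik)
        loaded = true_params.structure.loading_pattern.astype(bool)
        assert (params.a[loaded] > 0).all()
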