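"""Proportional-odds fits, DIF statistics, purification, impact curves."""

import numpy as np
import pytest
from scipy import special, stats

import caremirt as cm
from caremirt.cohort import DIFInjection, inject_dif
from caremirt.dif import (
    dif_impact,
    dif_statistics,
    monte_carlo_thresholds,
    proportional_odds_fit,
    purify,
)


def _simulate_po(n, beta, cuts, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta)))
    eta = X @ np.asarray(beta)
    p_le = special.expit(np.asarray(cuts)[None, :] - eta[:, None])
    P = np.diff(
        np.concatenate([np.zeros((n, 1)), p_le, np.ones((n, 1))], axis=1), axis=1
    )
    y = np.array([rng.choice(len(cuts) + 1, p=pi / pi.sum()) for pi in P]) + 1
    return y, X


class TestProportionalOdds:
    def test_intercept_only_reproduces_marginal_logits(self):
        y = np.array([1] * 10 + [2] * 20 + [3] * 30 + [4] * 25 + [5] * 15)
        fit = proportional_odds_fit(y, None)
        emp = np.array([np.mean(y <= k) for k in (1, 2, 3, 4)])
        assert np.allclose(fit.cutpoints, special.logit(emp), atol=1e-6)

    def test_recovers_known_coefficients(self):
        y, X = _simulate_po(5000, [1.0, 0.5], [-1.5, -0.5, 0.5, 1.5], 3)
        fit = proportional_odds_fit(y, X)
        assert np.abs(fit.coefficients - [1.0, 0.5]).max() < 0.1
        assert np.abs(fit.cutpoints - [-1.5, -0.5, 0.5, 1.5]).max() < 0.1

    def test_agrees_with_statsmodels_oracle(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        y, X = _simulate_po(400, [0.8, -0.4], [-1.0, 0.0, 1.0, 2.0], 5)
        mine = proportional_odds_fit(y, X)
        sm_fit = OrderedModel(y, X, distr="logit").fit(method="lbfgs", disp=0)
        assert mine.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert np.abs(mine.coefficients - sm_fit.params[:2]).max() < 1e-3

    def test_constant_column_rejected(self):
        y = np.array([1, 2, 3, 4, 5] * 10)
        with pytest.raises(ValueError, match="constant|rank"):
            proportional_odds_fit(y, np.zeros((50, 1)))

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            proportional_odds_fit(np.ones(30), None)


class TestDifStatistics:
    def test_lr_is_twice_loglik_difference(self):
        rng = np.random.default_rng(2)
        theta = rng.normal(size=300)
        group = rng.integers(2, size=300)
        y = np.clip(np.round(3 + theta + rng.normal(scale=1.0, size=300)), 1, 5)
        out = dif_statistics(y, theta, group)
        g = group.astype(float)
        m0 = proportional_odds_fit(y, theta[:, None])
        m1 = proportional_odds_fit(y, np.column_stack([theta, g]))
        assert out["lr_uniform"] == pytest.approx(
            2 * (max(m1.loglik, m0.loglik) - m0.loglik), abs=1e-6
        )

    def test_nested_loglik_ordering(self):
        rng = np.random.default_rng(4)
        theta = rng.normal(size=250)
        group = rng.integers(2, size=250)
        y = np.clip(np.round(3 + 0.8 * theta + rng.normal(size=250)), 1, 5)
        out = dif_statistics(y, theta, group)
        assert out["ll_m0"] <= out["ll_m1"] + 1e-8 <= out["ll_m2"] + 2e-8
        assert out["lr_total"] >= max(out["lr_uniform"], out["lr_nonuniform"]) - 1e-8

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            dif_statistics(np.array([1, 2, 3] * 10), np.zeros(30), np.zeros(30))

    def test_null_rejection_rate_matches_chi_square(self, true_params):
        """Permuting group labels gives the asymptotic chi-square null."""
        thetas = cm.sample_thetas(400, 0.5, 20)
        data = cm.sample_responses(true_params, thetas, 21)
        ability = cm.score_eap(true_params, data)
        comp = ability.composite()
        comp = (comp - comp.mean()) / comp.std()
        rng = np.random.default_rng(22)
        base_group = np.repeat([0, 1], 200)
        rej_u = rej_n = 0
        n_perm = 200
        for _ in range(n_perm):
            g = rng.permutation(base_group)
            out = dif_statistics(data.values[:, 0], comp, g)
            rej_u += out["p_uniform"] < 0.05
            rej_n += out["p_nonuniform"] < 0.05
        ci = stats.binom.interval(0.95, n_perm, 0.05)
        assert ci[0] <= rej_u <= ci[1]
        assert ci[0] <= rej_n <= ci[1]


class TestPurify:
    def test_null_data_converges_fast_with_few_flags(self, true_params):
        thetas = cm.sample_thetas(400, 0.5, 30)
        data = cm.sample_responses(true_params, thetas, 31)
        group = np.repeat([0, 1], 200)
        res = purify(data, true_params, group)
        assert res.iterations <= 3
        assert res.table["flag_any"].mean() <= 0.2  # ~alpha-level noise

    def test_injected_dif_item_is_flagged(self, true_params):
        ref, foc = inject_dif(true_params, DIFInjection(item=2, uniform_shift=0.8))
        thetas = cm.sample_thetas(1000, 0.5, 40)
        r_ref = cm.sample_responses(ref, thetas[:500], 41)
        r_foc = cm.sample_responses(foc, thetas[500:], 42)
        data = cm.ItemResponseMatrix(np.vstack([r_ref.values, r_foc.values]))
        group = np.repeat([0, 1], 500)
        res = purify(data, true_params, group)
        assert "item03" in res.flagged_items("uniform")

    def test_max_iter_zero_returns_initial_pass(self, true_params):
        thetas = cm.sample_thetas(300, 0.5, 50)
        data = cm.sample_responses(true_params, thetas, 51)
        group = np.repeat([0, 1], 150)
        res = purify(data, true_params, group, max_iter=0)
        assert res.iterations == 0

    def test_group_relabeling_leaves_statistics_unchanged(self, true_params):
        thetas = cm.sample_thetas(300, 0.5, 60)
        data = cm.sample_responses(true_params, thetas, 61)
        group = np.repeat([0, 1], 150)
        r1 = purify(data, true_params, group, max_iter=0)
        r2 = purify(data, true_params, 1 - group, max_iter=0)
        assert np.allclose(
            r1.table["lr_uniform"], r2.table["lr_uniform"], atol=1e-6
        )
        assert np.allclose(
            r1.table["lr_nonuniform"], r2.table["lr_nonuniform"], atol=1e-6
        )


class TestMonteCarloThresholds:
    @pytest.fixture(scope="class")
    def thresholds(self, true_params):
        return monte_carlo_thresholds(
            true_params, (200, 200), n_sims=120, alpha=0.05, seed=3
        )

    def test_near_chi_square_asymptotics(self, thresholds):
        # LR(df=1) 95th percentile is 3.84; empirical quantiles hover around it
        assert np.abs(np.median(thresholds.lr_uniform) - 3.84) < 1.5
        assert (thresholds.lr_uniform > 0).all()

    def test_reproducible(self, true_params, thresholds):
        again = monte_carlo_thresholds(
            true_params, (200, 200), n_sims=120, alpha=0.05, seed=3
        )
        assert np.array_equal(thresholds.lr_uniform, again.lr_uniform)

    def test_alpha_one_returns_minimum(self, true_params):
        thr = monte_carlo_thresholds(
            true_params, (150, 150), n_sims=100, alpha=1.0, seed=4
        )
        assert (thr.lr_uniform >= 0).all()
        thr95 = monte_carlo_thresholds(
            true_params, (150, 150), n_sims=100, alpha=0.05, seed=4
        )
        assert (thr.lr_uniform <= thr95.lr_uniform).all()

    def test_too_few_sims_rejected(self, true_params):
        with pytest.raises(ValueError):
            monte_carlo_thresholds(true_params, (100, 100), n_sims=50)


class TestDifImpact:
    def test_identical_parameters_zero_impact(self, true_params):
        grid = np.column_stack([np.linspace(-3, 3, 31)] * 2)
        out = dif_impact(true_params, true_params, grid)
        assert np.allclose(out["score_difference"], 0.0)
        assert np.allclose(out["impact_theta"], 0.0)

    def test_uniform_shift_bounded_by_item_span(self, true_params):
        ref, foc = inject_dif(true_params, DIFInjection(item=0, uniform_shift=0.5))
        grid = np.column_stack([np.linspace(-3, 3, 61)] * 2)
        out = dif_impact(ref, foc, grid)
        assert np.abs(out["score_difference"]).max() <= 4.0  # one 1..5 item
        assert (out["score_difference"] <= 0).all()  # harder item, lower scores

    def test_relabeling_negates_impact(self, true_params):
        ref, foc = inject_dif(true_params, DIFInjection(item=1, uniform_shift=0.4))
        grid = np.column_stack([np.linspace(-2, 2, 21)] * 2)
        ab = dif_impact(ref, foc, grid)["score_difference"].to_numpy()
        ba = dif_impact(foc, ref, grid)["score_difference"].to_numpy()
        assert np.allclose(ab, -ba, atol=1e-10)
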