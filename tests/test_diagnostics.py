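"""MDISC/MDIFF closed forms, Q3 screening, information surfaces, moments."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import caremirt as cm
from caremirt.diagnostics import (
    default_theta_grid,
    expected_item_score,
    information_surfaces,
    item_diagnostics_table,
    item_moments,
    mdiff,
    mdisc,
    mdisc_class,
    ordered_thresholds_report,
    q3_residual_correlations,
)


class TestMdisc:
    def test_pythagorean(self):
        assert mdisc(np.array([3.0, 4.0])) == pytest.approx(5.0, abs=1e-12)

    def test_boundary_classifications(self):
        assert mdisc_class(mdisc(np.array([1.5, 0.0]))) == "good"  # 1.5 is not > 1.5
        assert mdisc_class(0.0) == "poor"
        assert mdisc_class(0.5) == "moderate"
        assert mdisc_class(1.0) == "moderate"
        assert mdisc_class(1.51) == "excellent"

    def test_unidimensional_reduction(self):
        assert mdisc(np.array([0.0, 1.3])) == pytest.approx(1.3)


class TestMdiff:
    def test_direct_division(self):
        out = mdiff(np.array([2.0, 1.0, 0.0, -1.0]), 2.0)
        assert np.allclose(out, [-1.0, -0.5, 0.0, 0.5])

    def test_descending_d_gives_ascending_mdiff(self):
        d = np.array([2.0, 0.5, -0.3, -1.7])
        out = mdiff(d, 1.4)
        assert (np.diff(out) > 0).all()

    def test_zero_mdisc_rejected(self):
        with pytest.raises(ValueError):
            mdiff(np.array([1.0, 0.0, -1.0, -2.0]), 0.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_cumulative_prob_is_half_at_mdiff_point(self, seed):
        """At theta = MDIFF_k * a/||a||, boundary k has probability exactly 0.5."""
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.3, 2.5, size=2)
        d = np.sort(rng.normal(scale=1.5, size=4))[::-1]
        d[np.diff(d, prepend=d[0] + 1) >= 0] -= 1e-3
        p = cm.MGRMParameters(a[None, :], d[None, :], np.eye(2))
        m = mdisc(a)
        diffs = mdiff(d, m)
        u = a / m
        for k in range(4):
            pstar = cm.cumulative_prob(p, diffs[k] * u, 0)
            assert pstar[k] == pytest.approx(0.5, abs=1e-10)


class TestOrderedThresholds:
    def test_ordered_truth_all_ordered(self, true_params):
        report = ordered_thresholds_report(true_params)
        assert report["ordered"].all()
        assert (report["direction"] == "ascending").all()

    def test_swapped_pair_flagged(self, true_params):
        params = true_params.copy()
        # swap two MDIFF values on item 4 by editing d out-of-band
        object.__setattr__(params, "d", params.d.copy())
        params.d[4] = np.array([2.0, -0.5, 0.2, -1.8])  # not monotone after division
        report = ordered_thresholds_report(params)
        assert not report.loc[4, "ordered"]
        assert report.loc[4, "direction"] == "disordered"
        assert report.drop(index=4)["ordered"].all()

    def test_recovered_fits_keep_ordering(self, fitted_model):
        _, params, _, _ = fitted_model
        assert ordered_thresholds_report(params)["ordered"].all()


class TestQ3:
    def test_null_model_flag_rate_low(self, fitted_model):
        data, params, ability, _ = fitted_model
        q3 = q3_residual_correlations(params, ability, data)
        assert q3.flagged_proportion <= 0.05

    def test_duplicated_items_flagged(self, true_params):
        thetas = cm.sample_thetas(600, 0.5, 8)
        values = cm.sample_responses(true_params, thetas, 9).values.copy()
        values[:, 1] = values[:, 0]
        data = cm.ItemResponseMatrix(values)
        est, ability, _ = cm.fit(data, true_params.structure)
        q3 = q3_residual_correlations(est, ability, data)
        assert q3.values[0, 1] > 0.9
        assert ("item01", "item02") in [(a, b) for a, b, _ in q3.flagged_pairs]

    def test_flag_proportion_arithmetic(self, fitted_model):
        data, params, ability, _ = fitted_model
        q3 = q3_residual_correlations(params, ability, data, threshold=0.0)
        # threshold 0 flags every defined pair: 45 pairs for 10 items
        assert len(q3.flagged_pairs) == 45
        assert q3.flagged_proportion == pytest.approx(1.0)

    def test_symmetry_and_reorder_invariance(self, fitted_model):
        data, params, ability, _ = fitted_model
        q3 = q3_residual_correlations(params, ability, data)
        assert np.allclose(q3.values, q3.values.T, equal_nan=True)
        perm = np.arange(10)[::-1]
        data_p = cm.ItemResponseMatrix(
            data.values[:, perm], item_ids=[data.item_ids[i] for i in perm]
        )
        params_p = cm.MGRMParameters(
            params.a[perm], params.d[perm], params.latent_cov, params.structure
        )
        q3_p = q3_residual_correlations(params_p, ability, data_p)
        assert set(frozenset((a, b)) for a, b, _ in q3.flagged_pairs) == set(
            frozenset((a, b)) for a, b, _ in q3_p.flagged_pairs
        )

    def test_zero_variance_item_reported_undefined(self, true_params):
        # identical response rows give constant residual columns
        row = cm.sample_responses(true_params, np.zeros((1, 2)), 2).values
        data = cm.ItemResponseMatrix(np.tile(row, (50, 1)))
        ability = cm.score_eap(true_params, data)
        q3 = q3_residual_correlations(true_params, ability, data)
        assert q3.undefined_items
        assert all(np.isnan(v) for v in np.ravel(q3.values[~np.eye(10, dtype=bool)]))


class TestInformationSurfaces:
    def test_expected_total_bounds_and_monotonicity(self, true_params):
        line = np.column_stack([np.linspace(-4, 4, 81)] * 2)
        surf = information_surfaces(true_params, line)
        assert (surf["expected_total"] >= 10).all() and (surf["expected_total"] <= 50).all()
        assert (np.diff(surf["expected_total"]) > 0).all()

    def test_information_nonnegative_and_se_inverse(self, true_params):
        grid = default_theta_grid(-3, 3, 0.5)
        surf = information_surfaces(true_params, grid)
        assert (surf["information"] >= 0).all()
        assert np.allclose(surf["se"], 1 / np.sqrt(surf["information"]), rtol=1e-6)

    def test_information_peaks_midrange(self, true_params):
        """Centered thresholds concentrate precision on moderate trait levels."""
        line = np.column_stack([np.linspace(-4, 4, 161)] * 2)
        surf = information_surfaces(true_params, line)
        peak = surf.loc[surf["information"].idxmax(), "theta1"]
        assert -1.0 <= peak <= 1.0

    def test_zero_direction_rejected(self, true_params):
        with pytest.raises(ValueError):
            information_surfaces(true_params, np.zeros((1, 2)), direction=np.zeros(2))


class TestItemMoments:
    def test_symmetric_two_point_data(self):
        data = cm.ItemResponseMatrix(np.array([[1], [5], [1], [5]]), k_per_item=[5])
        mom = item_moments(data)
        assert mom.loc[0, "skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_undefined(self):
        data = cm.ItemResponseMatrix(np.full((10, 1), 3), k_per_item=[5])
        mom = item_moments(data)
        assert not mom.loc[0, "defined"]
        assert np.isnan(mom.loc[0, "skewness"])

    def test_matches_textbook_formulas_on_fixture(self):
        values = np.array([1, 1, 2, 2, 2, 3, 3, 3, 3, 4, 4, 4, 5, 5, 2, 3, 1, 4, 3, 2])
        data = cm.ItemResponseMatrix(values[:, None], k_per_item=[5])
        mom = item_moments(data)
        x = values.astype(float)
        m = x.mean()
        m2 = ((x - m) ** 2).mean()
        m3 = ((x - m) ** 3).mean()
        m4 = ((x - m) ** 4).mean()
        assert mom.loc[0, "mean"] == pytest.approx(m)
        assert mom.loc[0, "sd"] == pytest.approx(np.sqrt(m2))
        assert mom.loc[0, "skewness"] == pytest.approx(m3 / m2**1.5)
        assert mom.loc[0, "excess_kurtosis"] == pytest.approx(m4 / m2**2 - 3)


class TestDiagnosticsTable:
    def test_reference_parameters_mostly_excellent(self, true_params):
        diag = item_diagnostics_table(true_params)
        assert (diag.mdisc >= 1.4).all()
        assert diag.thresholds_ordered.all()
        assert set(diag.mdisc_class) <= {"good", "excellent"}
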