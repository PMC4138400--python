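"""Percent change, correlation, regression influence, agreement, t-tests."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gripscore.exceptions import (
    DegenerateInputError,
    InvalidParameterError,
    ShapeMismatchError,
)
from gripscore.stats import (
    bland_altman,
    cooks_distance,
    fit_simple_regression,
    flag_outliers,
    improvement_magnitude,
    pearson,
    percent_improvement,
    welch_t_test,
)


class TestPercentImprovement:
    def test_no_change_is_zero(self):
        assert percent_improvement(10.0, 10.0) == 0.0

    def test_error_drop_is_negative(self):
        assert percent_improvement(10.0, 8.0) == pytest.approx(-0.20)
        assert improvement_magnitude(10.0, 8.0) == pytest.approx(0.20)

    def test_worsening_group_means(self):
        # plug-in arithmetic on the printed formula with 11.24 -> 12.41
        assert percent_improvement(11.24, 12.41) == pytest.approx(0.1041, abs=5e-5)

    def test_zero_baseline_rejected(self):
        with pytest.raises(InvalidParameterError):
            percent_improvement(0.0, 5.0)

    @given(st.floats(0.01, 100), st.floats(0.0, 100), st.floats(0.01, 50))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, pre, post, c):
        assert percent_improvement(c * pre, c * post) == pytest.approx(
            percent_improvement(pre, post), rel=1e-9, abs=1e-9
        )


def pearson_oracle(x, y):
    """Direct covariance/stddev formula with the t-distribution p-value."""
    x, y = np.asarray(x), np.asarray(y)
    n = x.size
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    r = cov / (x.std() * y.std())
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return r, p


class TestPearson:
    def test_perfect_positive_linear(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = pearson(x, y)
        r, p = pearson_oracle(x, y)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.n == 10

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_and_sign_flip(self, seed, a, b):
        r = np.random.default_rng(seed)
        x = r.normal(size=12)
        y = r.normal(size=12)
        base = pearson(x, y).r
        assert pearson(a * x + b, y).r == pytest.approx(base, abs=1e-9)
        assert pearson(-x, y).r == pytest.approx(-base, abs=1e-9)


class TestSimpleRegression:
    def test_collinear_points_fit_exactly(self):
        x = np.arange(5.0)
        diag = fit_simple_regression(x, 3 * x - 1)
        assert diag.rmse_s == 0.0
        assert np.allclose(diag.residuals, 0.0)
        assert np.all(diag.cooks_d == 0.0)

    def test_normal_equation_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0, 10.0])
        n = x.size
        # closed-form normal equations
        slope = (n * np.sum(x * y) - x.sum() * y.sum()) / (n * np.sum(x * x) - x.sum() ** 2)
        intercept = (y.sum() - slope * x.sum()) / n
        diag = fit_simple_regression(x, y)
        assert diag.slope == pytest.approx(slope, abs=1e-12)
        assert diag.intercept == pytest.approx(intercept, abs=1e-12)
        assert diag.residuals.sum() == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_dataset_same_line(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        a = fit_simple_regression(x, y)
        b = fit_simple_regression(np.r_[x, x], np.r_[y, y])
        assert b.slope == pytest.approx(a.slope, abs=1e-12)
        assert b.intercept == pytest.approx(a.intercept, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_simple_regression([2.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])


class TestCooksDistance:
    def test_point_on_line_of_others_has_zero_distance(self):
        # first four points define y = x exactly; fifth sits on that line too
        x = np.array([0.0, 1.0, 2.0, 3.0, 1.5])
        y = np.array([0.0, 1.0, 2.0, 3.1, 1.5])
        diag = fit_simple_regression(x, y)
        # removing a zero-influence point must leave the line unchanged
        zero_i = int(np.argmin(diag.cooks_d))
        keep = np.ones(5, dtype=bool)
        keep[zero_i] = False
        reduced = fit_simple_regression(x[keep], y[keep])
        if diag.cooks_d[zero_i] < 1e-20:
            assert reduced.slope == pytest.approx(diag.slope, abs=1e-12)
            assert reduced.intercept == pytest.approx(diag.intercept, abs=1e-12)

    def test_gross_outlier_dominates_and_closed_form_agrees(self, rng):
        x = np.linspace(0, 7, 8)
        y = 2 * x + rng.normal(0, 0.1, size=8)
        y[5] += 25.0
        diag = fit_simple_regression(x, y)
        assert int(np.argmax(diag.cooks_d)) == 5
        h = diag.leverage
        closed = diag.residuals**2 * h / (2 * diag.rmse_s**2 * (1 - h) ** 2)
        assert np.allclose(diag.cooks_d, closed, atol=1e-10)

    def test_symmetric_configuration_gives_equal_distances(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([-1.0, 1.0, 1.0, -1.0])
        diag = fit_simple_regression(x, y)
        assert np.allclose(diag.cooks_d, diag.cooks_d[0])

    def test_matches_statsmodels_influence(self, rng):
        import statsmodels.api as sm
        from statsmodels.stats.outliers_influence import OLSInfluence

        x = rng.normal(size=15)
        y = 1.5 * x + rng.normal(size=15)
        diag = fit_simple_regression(x, y)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        sm_d = OLSInfluence(fit).cooks_distance[0]
        assert np.allclose(diag.cooks_d, sm_d, atol=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_leave_one_out_equals_closed_form_randomised(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(8, 30))
        x = r.normal(size=n)
        y = r.normal(size=n) + r.normal() * x
        diag = fit_simple_regression(x, y)  # raises internally on disagreement
        h = diag.leverage
        closed = diag.residuals**2 * h / (2 * diag.rmse_s**2 * (1 - h) ** 2)
        assert np.allclose(diag.cooks_d, closed, rtol=1e-8, atol=1e-10)

    def test_too_small_refit_rejected(self):
        x = np.array([0.0, 1.0, 2.0])
        diag_like = fit_simple_regression(np.arange(4.0), np.array([0, 1, 2.5, 3]))
        object.__setattr__(diag_like, "n", 3)
        with pytest.raises(DegenerateInputError):
            cooks_distance(diag_like, x, x)


class TestFlagOutliers:
    def test_threshold_arithmetic(self):
        # n=22, k=1 -> 4/20 = 0.2
        d = np.array([0.19] * 21 + [0.2])
        flags = flag_outliers(d, n=22)
        assert flags.sum() == 1 and flags[-1]

    def test_no_flags_when_all_zero(self):
        assert not flag_outliers(np.zeros(10), n=10).any()

    def test_inclusive_at_exact_threshold(self):
        flags = flag_outliers([0.01, 0.5], n=10, k=1)  # threshold 4/8 = 0.5
        assert flags.tolist() == [False, True]

    def test_degenerate_n_rejected(self):
        with pytest.raises(InvalidParameterError):
            flag_outliers([0.1, 0.1], n=2)


class TestBlandAltman:
    def test_identical_measures_collapse(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        res = bland_altman(a, a)
        assert res.bias == 0.0
        assert res.loa_lower == 0.0 == res.loa_upper

    def test_constant_shift_gives_bias(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        res = bland_altman(a, a + 0.26)
        assert res.bias == pytest.approx(-0.26)

    def test_direct_mean_sd_oracle(self, rng):
        a = rng.uniform(0, 1, 12)
        b = rng.uniform(0, 1, 12)
        res = bland_altman(a, b)
        d = a - b
        mean, sd = d.mean(), d.std(ddof=1)
        assert res.bias == pytest.approx(mean, abs=1e-12)
        assert res.sd_diff == pytest.approx(sd, abs=1e-12)
        assert res.loa_upper == pytest.approx(mean + 1.96 * sd, abs=1e-12)
        assert res.loa_lower == pytest.approx(mean - 1.96 * sd, abs=1e-12)
        assert res.bias_ci[1] - res.bias_ci[0] == pytest.approx(
            2 * 1.96 * sd / np.sqrt(12), abs=1e-12
        )

    def test_limit_width_identity(self, rng):
        a = rng.uniform(0, 1, 9)
        b = rng.uniform(0, 1, 9)
        res = bland_altman(a, b)
        assert res.loa_upper - res.loa_lower == pytest.approx(3.92 * res.sd_diff, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            bland_altman([0.1, 0.2, 0.3], [0.1, 0.2])


def welch_oracle(a, b):
    """Textbook Welch statistic and Welch–Satterthwaite degrees of freedom."""
    a, b = np.asarray(a), np.asarray(b)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2 * sps.t.sf(abs(t), dof)
    return t, dof, p


class TestWelchTTest:
    def test_identical_samples_no_difference(self):
        a = [1.0, 2.0, 3.0]
        res = welch_t_test(a, a)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_swap_antisymmetry(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 2, 9)
        ab = welch_t_test(a, b)
        ba = welch_t_test(b, a)
        assert ba.t_statistic == pytest.approx(-ab.t_statistic, abs=1e-12)
        assert ba.p_value == pytest.approx(ab.p_value, abs=1e-12)

    def test_textbook_formula_oracle(self):
        a = [11.2, 9.8, 14.1, 8.6, 12.3]
        b = [7.1, 6.5, 8.2, 7.7, 6.9]
        res = welch_t_test(a, b)
        t, dof, p = welch_oracle(a, b)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.dof == pytest.approx(dof, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_pooled_variant_matches_classic_formula(self, rng):
        a = rng.normal(0, 1, 7)
        b = rng.normal(0.5, 1, 5)
        res = welch_t_test(a, b, variant="pooled")
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.dof == a.size + b.size - 2

    def test_tiny_sample_rejected(self):
        with pytest.raises(InvalidParameterError):
            welch_t_test([1.0], [1.0, 2.0])
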