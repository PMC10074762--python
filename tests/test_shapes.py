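"""Polynomial shape fits, the nested F-test and the selection ladder."""

import numpy as np
import pytest
from scipy import stats

import revpitch as rp
from revpitch.shapes import normalized_grid


class TestFitPolynomial:
    def test_exact_linear_data(self):
        t = normalized_grid(6)
        fit = rp.fit_polynomial(3.0 - 2.0 * t, 1)
        assert fit.sse == pytest.approx(0.0, abs=1e-20)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficients == pytest.approx([3.0, -2.0])

    def test_hand_ols_example(self):
        # normal-equations solution frozen by hand for y on an explicit grid
        fit = rp.fit_polynomial([1, 2, 2, 3], 1, t=[0, 1, 2, 3])
        assert fit.coefficients == pytest.approx([1.1, 0.6])
        assert fit.sse == pytest.approx(0.2)

    def test_nested_sse_monotone(self, rng):
        y = rng.normal(size=8)
        sses = [rp.fit_polynomial(y, d).sse for d in (1, 2, 3, 4)]
        assert all(a >= b - 1e-12 for a, b in zip(sses, sses[1:]))

    def test_degree_too_high_rejected(self):
        with pytest.raises(ValueError):
            rp.fit_polynomial([1.0, 2.0, 3.0], 3)

    def test_matches_statsmodels_ols(self, rng):
        """Independent cross-check against the statsmodels OLS machinery."""
        import statsmodels.api as sm

        y = rng.normal(size=8)
        t = normalized_grid(8)
        fit = rp.fit_polynomial(y, 3)
        X = sm.add_constant(np.column_stack([t, t**2, t**3]))
        ols = sm.OLS(y, X).fit()
        assert fit.coefficients == pytest.approx(ols.params, abs=1e-8)
        assert fit.sse == pytest.approx(ols.ssr)
        assert fit.r_squared == pytest.approx(ols.rsquared)


class TestNestedFTest:
    def test_symmetric_data_quadratic_contrast_is_zero(self):
        fits = [rp.fit_polynomial([1, 2, 2, 3], d, t=[0, 1, 2, 3]) for d in (1, 2)]
        res = rp.nested_f_test(fits[0], fits[1])
        assert res.f_stat == pytest.approx(0.0, abs=1e-9)
        assert res.winner == 1

    def test_equal_sse_gives_f_zero_p_one(self):
        small = rp.ShapeFit(degree=1, coefficients=np.array([0.0, 1.0]),
                            sse=2.0, r_squared=0.5, n_points=8)
        big = rp.ShapeFit(degree=3, coefficients=np.zeros(4),
                          sse=2.0, r_squared=0.5, n_points=8)
        res = rp.nested_f_test(small, big)
        assert res.f_stat == 0.0
        assert res.p_value == 1.0
        assert res.winner == 1

    def test_matches_statsmodels_compare_f_test(self, rng):
        import statsmodels.api as sm

        t = np.tile(normalized_grid(8), 4)
        y = 3 * t**3 - t + rng.normal(0, 0.3, size=t.size)
        f_small = rp.fit_polynomial(y, 1, t=t)
        f_big = rp.fit_polynomial(y, 3, t=t)
        res = rp.nested_f_test(f_small, f_big)
        Xs = sm.add_constant(t)
        Xb = sm.add_constant(np.column_stack([t, t**2, t**3]))
        f_ref, p_ref, df_ref = sm.OLS(y, Xb).fit().compare_f_test(
            sm.OLS(y, Xs).fit())
        assert res.f_stat == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)
        assert res.df_num == int(df_ref)

    def test_f_equals_likelihood_ratio_form(self, rng):
        """For Gaussian OLS, F and the log-likelihood ratio are one-to-one."""
        y = rng.normal(size=8) + normalized_grid(8) ** 3
        f1 = rp.fit_polynomial(y, 1)
        f3 = rp.fit_polynomial(y, 3)
        res = rp.nested_f_test(f1, f3)
        n = len(y)
        # LR statistic from profiled Gaussian likelihoods
        lr = n * (np.log(f1.sse) - np.log(f3.sse))
        f_from_lr = (np.exp(lr / n) - 1) * res.df_den / res.df_num
        assert res.f_stat == pytest.approx(f_from_lr)

    def test_power_against_cubic_signal(self):
        """Pooled cubic kernels: linear-vs-cubic significant almost always."""
        gen = np.random.default_rng(11)
        t = np.tile(normalized_grid(8), 32)
        signal = rp.make_template("cubic", 8)
        sig_sd = signal.std()
        hits = 0
        for _ in range(100):
            y = np.tile(signal, 32) + gen.normal(0, 0.1 * sig_sd, size=t.size)
            res = rp.nested_f_test(rp.fit_polynomial(y, 1, t=t),
                                   rp.fit_polynomial(y, 3, t=t))
            hits += res.significant
        assert hits >= 95

    def test_perfect_big_fit_rejected(self):
        y = normalized_grid(5) ** 2
        with pytest.raises(ValueError):
            rp.nested_f_test(rp.fit_polynomial(y, 1), rp.fit_polynomial(y, 4))


class TestSelectShape:
    def test_linear_data_selects_linear(self):
        gen = np.random.default_rng(3)
        t = np.tile(normalized_grid(8), 16)
        y = 2.0 * t + gen.normal(0, 0.01, size=t.size)
        best, ladder = rp.select_shape(y, t=t)
        assert best == 1
        assert not any(step.significant for step in ladder)

    @pytest.mark.parametrize("shape,degree", [("cubic", 3), ("quartic", 4)])
    def test_ladder_recovers_generating_shape(self, shape, degree):
        gen = np.random.default_rng(17)
        signal = rp.make_template(shape, 8)
        t = np.tile(normalized_grid(8), 32)
        hits = 0
        for _ in range(100):
            y = np.tile(signal, 32) + gen.normal(0, 0.5 * signal.std(),
                                                 size=t.size)
            best, _ = rp.select_shape(y, t=t)
            hits += best == degree
        assert hits >= 90

    def test_quartic_ladder_reaches_linear_vs_quartic(self):
        gen = np.random.default_rng(23)
        signal = rp.make_template("quartic", 8)
        t = np.tile(normalized_grid(8), 32)
        y = np.tile(signal, 32) + gen.normal(0, 0.3 * signal.std(), size=t.size)
        best, ladder = rp.select_shape(y, t=t)
        assert best == 4
        comparisons = [step.comparison for step in ladder]
        assert "Linear and Quartic" in comparisons

    def test_ladder_invariant_to_affine_time_rescale(self, rng):
        y = rng.normal(size=32)
        t = np.tile(normalized_grid(8), 4)
        best1, ladder1 = rp.select_shape(y, t=t)
        best2, ladder2 = rp.select_shape(y, t=5.0 + 3.0 * t)
        assert best1 == best2
        for s1, s2 in zip(ladder1, ladder2):
            assert s1.f_stat == pytest.approx(s2.f_stat, rel=1e-6)


class TestShapeParams:
    def test_linear_polynomial(self):
        fit = rp.fit_polynomial(2.0 * normalized_grid(8), 1)
        params = rp.shape_params(fit)
        assert params.b0 == pytest.approx(0.0, abs=1e-12)
        assert params.midpoint_slope == pytest.approx(2.0)

    def test_odd_cubic_has_flat_midpoint_tangent(self):
        y = (2 * normalized_grid(8) - 1) ** 3
        params = rp.shape_params(rp.fit_polynomial(y, 3))
        assert params.midpoint_slope == pytest.approx(0.0, abs=1e-10)

    def test_recovery_from_noisy_cohorts(self):
        """b0 and midpoint slope recovered with small bias from cohorts
        generated by a known cubic."""
        gen = np.random.default_rng(31)
        t = normalized_grid(8)
        true_coef = np.array([1.0, -4.0, 9.0, -6.0])  # ascending powers
        truth = np.polynomial.polynomial.polyval(t, true_coef)
        true_params = rp.shape_params(
            rp.fit_polynomial(truth, 3))
        b0s, slopes = [], []
        for _ in range(20):
            est_b0, est_sl = [], []
            for _ in range(32):
                y = truth + gen.normal(0, 0.1 * truth.std(), size=8)
                p = rp.shape_params(rp.fit_polynomial(y, 3))
                est_b0.append(p.b0)
                est_sl.append(p.midpoint_slope)
            b0s.append(np.mean(est_b0))
            slopes.append(np.mean(est_sl))
        tol = 0.05 * abs(true_params.midpoint_slope)
        assert abs(np.mean(slopes) - true_params.midpoint_slope) < tol
        assert abs(np.mean(b0s) - true_params.b0) < tol
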