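"""Log-log OLS, bootstrap, isometry tests, Bayesian regression."""

import numpy as np
import pytest

from spiroscale import scaling as sc


def power_law(masses, intercept, slope, noise_sd=0.0, rng=None):
    x = np.log10(np.asarray(masses, dtype=float))
    eps = 0.0 if rng is None else noise_sd * rng.standard_normal(len(x))
    return 10.0 ** (intercept + slope * x + eps)


MASSES_17 = np.logspace(np.log10(0.097), np.log10(18.0), 17)


class TestLoglogOLS:
    def test_exact_on_noiseless_power_law(self):
        y = power_law(MASSES_17, 0.5, 0.67)
        fit = sc.loglog_ols(MASSES_17, y)
        assert fit.slope == pytest.approx(0.67, abs=1e-12)
        assert fit.intercept == pytest.approx(0.5, abs=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_two_point_line(self):
        fit = sc.loglog_ols([1.0, 10.0], [10.0, 100.0])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        y = power_law(MASSES_17, 0.2, 0.4, 0.15, rng)
        fit = sc.loglog_ols(MASSES_17, y)
        # closed-form normal equations, built independently
        X = np.column_stack([np.ones(17), np.log10(MASSES_17)])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log10(y))
        resid = np.log10(y) - X @ beta
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        assert fit.residual_sd == pytest.approx(
            np.sqrt(resid @ resid / 15), abs=1e-10
        )

    def test_degenerate_design_rejected(self):
        with pytest.raises(sc.DegenerateDesignError):
            sc.loglog_ols([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_scale_equivariance(self, rng):
        y = power_law(MASSES_17, 0.1, 0.7, 0.1, rng)
        f1 = sc.loglog_ols(MASSES_17, y)
        f2 = sc.loglog_ols(MASSES_17, 1000.0 * y)
        assert f2.slope == pytest.approx(f1.slope, abs=1e-12)
        assert f2.intercept == pytest.approx(f1.intercept + 3.0, abs=1e-10)


class TestBootstrap:
    def test_noiseless_data_gives_zero_width_ci(self):
        y = power_law(MASSES_17, 0.5, 0.67)
        b = sc.bootstrap_fit(MASSES_17, y, B=500, seed=3)
        lo, hi = b.ci("slope")
        assert lo == pytest.approx(0.67, abs=1e-10)
        assert hi == pytest.approx(0.67, abs=1e-10)

    def test_seeded_determinism(self, rng):
        y = power_law(MASSES_17, 0.3, 0.5, 0.1, rng)
        b1 = sc.bootstrap_fit(MASSES_17, y, B=1000, seed=11)
        b2 = sc.bootstrap_fit(MASSES_17, y, B=1000, seed=11)
        assert np.array_equal(b1.slope_samples, b2.slope_samples)
        assert np.array_equal(b1.resid_sd_samples, b2.resid_sd_samples)

    def test_ci_endpoints_are_order_statistics(self, rng):
        y = power_law(MASSES_17, 0.3, 0.5, 0.1, rng)
        b = sc.bootstrap_fit(MASSES_17, y, B=2000, seed=5)
        lo, hi = b.ci("slope")
        assert lo == pytest.approx(np.quantile(b.slope_samples, 0.025))
        assert hi == pytest.approx(np.quantile(b.slope_samples, 0.975))
        assert lo <= np.median(b.slope_samples) <= hi

    def test_p_value_extremes(self, rng):
        y = power_law(MASSES_17, 0.3, 0.5, 0.05, rng)
        b = sc.bootstrap_fit(MASSES_17, y, B=1000, seed=7)
        assert b.p_vs(-10.0) == 0.0  # all samples above
        assert b.p_vs(float(np.median(b.slope_samples))) == pytest.approx(1.0, abs=0.01)

    def test_p_and_ci_consistent(self, rng):
        for trial in range(20):
            y = power_law(MASSES_17, 0.3, 0.8, 0.1, rng)
            b = sc.bootstrap_fit(MASSES_17, y, B=2000, seed=trial)
            lo, hi = b.ci("slope")
            for ref in (0.33, 0.67, 1.0):
                if ref < lo or ref > hi:
                    assert sc.isometry_test(b, ref) < 0.05 + 1e-9

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            sc.bootstrap_fit([1.0, 2.0], [1.0, 2.0], B=100, seed=0)

    def test_type_i_error_calibrated(self, rng):
        """Isometric truth rejected at 5% in roughly 5% of simulations."""
        rejections = 0
        nsim = 200
        for i in range(nsim):
            y = power_law(MASSES_17, 0.5, 0.67, 0.1, rng)
            b = sc.bootstrap_fit(MASSES_17, y, B=500, seed=1000 + i)
            if sc.isometry_test(b, 0.67) < 0.05:
                rejections += 1
        assert 0.01 <= rejections / nsim <= 0.15

    def test_power_against_hypermetric_truth(self, rng):
        """Area exponent 0.9 should usually reject isometry (0.67)."""
        rejections = 0
        nsim = 100
        for i in range(nsim):
            y = power_law(MASSES_17, 0.5, 0.9, 0.1, rng)
            b = sc.bootstrap_fit(MASSES_17, y, B=500, seed=2000 + i)
            if sc.isometry_test(b, 0.67) < 0.05:
                rejections += 1
        assert rejections / nsim > 0.5


class TestRelativeVariability:
    def test_perfect_fit_is_zero(self):
        y = power_law(MASSES_17, 0.5, 0.67)
        assert sc.relative_variability(sc.loglog_ols(MASSES_17, y)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_hand_arithmetic(self):
        fit = sc.ScalingFit(slope=0.5, intercept=1.0, residual_sd=0.1, n=10)
        assert sc.relative_variability(fit) == pytest.approx(0.01)

    def test_noise_ordering_preserved(self, rng):
        """Tight anterior-like scatter scores lower than loose posterior."""
        y_tight = power_law(MASSES_17, -2.5, 0.67, 0.05, rng)
        y_loose = power_law(MASSES_17, -2.5, 0.67, 0.25, rng)
        rv_tight = sc.relative_variability(sc.loglog_ols(MASSES_17, y_tight))
        rv_loose = sc.relative_variability(sc.loglog_ols(MASSES_17, y_loose))
        assert rv_tight < rv_loose

    def test_bootstrap_summary_brackets_point_value(self, rng):
        y = power_law(MASSES_17, -1.0, 0.67, 0.1, rng)
        b = sc.bootstrap_fit(MASSES_17, y, B=2000, seed=9)
        med, lo, hi = sc.relative_variability(b)
        assert lo <= med <= hi


class TestBayes:
    def test_likelihood_dominance(self, rng):
        """Strong data (n=200, tiny noise) pins the posterior at OLS."""
        m = np.logspace(-1, 1, 200)
        y = power_law(m, 0.5, 0.67, 0.01, rng)
        ols = sc.loglog_ols(m, y)
        post = sc.bayes_loglog(m, y, draws=1500, seed=4)
        assert post.slope_median == pytest.approx(ols.slope, abs=0.01)
        assert post.intercept_median == pytest.approx(ols.intercept, abs=0.01)
        lo, hi = post.hpd("slope", 0.95)
        assert lo <= 0.67 <= hi

    def test_prior_only_recovers_prior_moments(self):
        post = sc.bayes_loglog(None, None, draws=4000, seed=8)
        pri = sc.DEFAULT_PRIORS
        assert np.mean(post.slope_samples) == pytest.approx(pri.slope_mu, abs=0.5)
        assert np.std(post.slope_samples) == pytest.approx(pri.slope_sd, rel=0.15)
        # HalfNormal(1) has mean sqrt(2/pi) ~ 0.798
        assert np.mean(post.sigma_samples) == pytest.approx(0.798, abs=0.1)
        assert np.all(post.sigma_samples > 0)

    def test_seeded_determinism(self, rng):
        y = power_law(MASSES_17, 0.3, 0.5, 0.1, rng)
        p1 = sc.bayes_loglog(MASSES_17, y, draws=500, seed=13)
        p2 = sc.bayes_loglog(MASSES_17, y, draws=500, seed=13)
        assert np.array_equal(p1.slope_samples, p2.slope_samples)

    def test_hpd_is_ordered_and_contains_median(self, rng):
        y = power_law(MASSES_17, 0.3, 0.5, 0.1, rng)
        post = sc.bayes_loglog(MASSES_17, y, draws=1000, seed=14)
        for prob in (0.94, 0.95):
            lo, hi = post.hpd("slope", prob)
            assert lo < post.slope_median < hi

    def test_ess_reported(self, rng):
        y = power_law(MASSES_17, 0.3, 0.5, 0.1, rng)
        post = sc.bayes_loglog(MASSES_17, y, draws=1000, seed=15)
        assert set(post.ess) == {"slope", "intercept", "sigma"}
        assert all(v > 0 for v in post.ess.values())
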