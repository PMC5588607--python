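"""Analysis models: GLM kernels vs statsmodels, closed forms, Rubin pooling."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from rrmi import (
    cca_fit,
    choose_analysis,
    delete_imputed_outcomes,
    fit_log_binomial,
    fit_modified_poisson,
    pool_rubin,
)
from rrmi._glm import FitError, fit_logistic
from rrmi.datagen import SimDataset
from rrmi.estimators import LOG_BINOMIAL, MODIFIED_POISSON, FitResult
from rrmi.fcs import ImputationSet


def _dataset(y, x1, x2, miss_y=None, miss_x2=None):
    n = len(y)
    return SimDataset(
        np.asarray(y, dtype=float),
        np.asarray(x1, dtype=float),
        np.asarray(x2, dtype=float),
        np.zeros(n, dtype=bool) if miss_y is None else np.asarray(miss_y),
        np.zeros(n, dtype=bool) if miss_x2 is None else np.asarray(miss_x2),
    )


def _simulate(rng, n=800, b0=-2.0, b1=0.7, b2=0.5, binary=True):
    if binary:
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = (rng.random(n) < 0.5).astype(float)
    else:
        x1 = rng.normal(0, 0.45, n)
        x2 = rng.normal(0, 0.45, n)
    eta = np.minimum(b0 + b1 * x1 + b2 * x2, -1e-6)
    y = (rng.random(n) < np.exp(eta)).astype(float)
    return _dataset(y, x1, x2)


class TestLogBinomial:
    def test_matches_statsmodels_glm(self, rng):
        ds = _simulate(rng)
        fit = fit_log_binomial(ds)
        X = np.column_stack([np.ones(ds.n), ds.x1, ds.x2])
        ref = sm.GLM(ds.y, X, family=sm.families.Binomial(sm.families.links.Log())).fit()
        np.testing.assert_allclose(fit.estimates, ref.params, atol=1e-5)
        np.testing.assert_allclose(fit.std_errors, ref.bse, rtol=1e-4)
        assert fit.converged

    def test_saturated_two_by_two_equals_sample_log_rr(self, rng):
        x = (rng.random(600) < 0.5).astype(float)
        y = (rng.random(600) < np.where(x == 1, 0.4, 0.2)).astype(float)
        ds = _dataset(y, x, np.zeros(600))
        # X2 constant: drop it by fitting on (1, x1) manually through the kernel
        from rrmi._glm import fit_log_binomial_irls

        X = np.column_stack([np.ones(600), x])
        beta, _, conv = fit_log_binomial_irls(X, y)
        p1, p0 = y[x == 1].mean(), y[x == 0].mean()
        assert beta[1] == pytest.approx(math.log(p1 / p0), abs=1e-8)
        assert conv

    def test_constant_outcome_raises(self):
        ds = _dataset(np.ones(20), np.arange(20) % 2, np.zeros(20))
        with pytest.raises(FitError):
            fit_log_binomial(ds)

    def test_boundary_fit_flagged_not_converged(self, rng):
        # risk hits 1 in one cell: the MLE sits on the boundary of the log link
        x = np.repeat([0.0, 1.0], 50)
        y = np.where(x == 1, 1.0, (rng.random(100) < 0.3).astype(float))
        ds = _dataset(y, x, np.zeros(100))
        from rrmi._glm import fit_log_binomial_irls

        X = np.column_stack([np.ones(100), x])
        beta, _, conv = fit_log_binomial_irls(X, y)
        assert not conv


class TestModifiedPoisson:
    def test_matches_statsmodels_hc0(self, rng):
        ds = _simulate(rng, binary=False)
        fit = fit_modified_poisson(ds)
        X = np.column_stack([np.ones(ds.n), ds.x1, ds.x2])
        ref = sm.GLM(ds.y, X, family=sm.families.Poisson()).fit(cov_type="HC0")
        np.testing.assert_allclose(fit.estimates, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.std_errors, ref.bse, rtol=1e-5)

    def test_intercept_only_sandwich_closed_form(self, rng):
        y = (rng.random(500) < 0.25).astype(float)
        from rrmi._glm import fit_poisson_hc0

        X = np.ones((500, 1))
        beta, cov, _ = fit_poisson_hc0(X, y)
        ybar = y.mean()
        assert beta[0] == pytest.approx(math.log(ybar), abs=1e-8)
        assert cov[0, 0] == pytest.approx((1 - ybar) / (500 * ybar), rel=1e-6)

    def test_sandwich_matches_delta_method_two_by_two(self, rng):
        x = np.repeat([0.0, 1.0], 300)
        y = (rng.random(600) < np.where(x == 1, 0.4, 0.2)).astype(float)
        from rrmi._glm import fit_poisson_hc0

        X = np.column_stack([np.ones(600), x])
        beta, cov, _ = fit_poisson_hc0(X, y)
        p1, p0 = y[x == 1].mean(), y[x == 0].mean()
        n1 = n0 = 300
        delta = (1 - p1) / (n1 * p1) + (1 - p0) / (n0 * p0)
        assert cov[1, 1] == pytest.approx(delta, abs=1e-8)

    def test_point_estimates_agree_with_log_binomial_saturated(self, rng):
        # saturated 2x2 design: both MLEs equal the sample log risk ratio
        from rrmi._glm import fit_log_binomial_irls, fit_poisson_hc0

        x = np.repeat([0.0, 1.0], 250)
        y = (rng.random(500) < np.where(x == 1, 0.45, 0.15)).astype(float)
        X = np.column_stack([np.ones(500), x])
        lb, _, _ = fit_log_binomial_irls(X, y)
        mp, _, _ = fit_poisson_hc0(X, y)
        np.testing.assert_allclose(lb, mp, atol=1e-6)


class TestLogistic:
    def test_matches_statsmodels_logit(self, rng):
        n = 500
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        X = np.column_stack([np.ones(n), x])
        beta, cov, conv = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(cov)), ref.bse, rtol=1e-5)
        assert conv

    def test_separation_raises(self):
        x = np.linspace(-1, 1, 40)
        y = (x > 0).astype(float)
        with pytest.raises(FitError):
            fit_logistic(np.column_stack([np.ones(40), x]), y)


class TestChooseAnalysis:
    def test_binary_converged_fit_returned_unchanged(self, rng):
        ds = _simulate(rng)
        lb = fit_log_binomial(ds)
        out = choose_analysis(ds, "binary", fit_lb=lb)
        assert out is lb
        assert out.estimator == LOG_BINOMIAL

    def test_continuous_always_modified_poisson(self, rng):
        ds = _simulate(rng, binary=False)
        assert choose_analysis(ds, "continuous").estimator == MODIFIED_POISSON

    def test_nonconverged_falls_back_to_modified_poisson(self, rng):
        ds = _simulate(rng)
        bad = FitResult(np.zeros(3), np.ones(3), False, LOG_BINOMIAL, ds.n)
        out = choose_analysis(ds, "binary", fit_lb=bad)
        assert out.estimator == MODIFIED_POISSON


class TestRubinPooling:
    def test_worked_m2_arithmetic(self):
        fits = [
            FitResult(np.array([0.0, 0.0, 0.0]), np.array([1.0, 1.0, 1.0]), True, LOG_BINOMIAL, 10),
            FitResult(np.array([2.0, 2.0, 2.0]), np.array([1.0, 1.0, 1.0]), True, LOG_BINOMIAL, 10),
        ]
        pooled = pool_rubin(fits)
        assert pooled.estimates[1] == pytest.approx(1.0)
        assert pooled.total_variance[1] == pytest.approx(4.0)  # W=1, B=2, T=1+1.5*2
        assert pooled.dof[1] == pytest.approx(16 / 9)

    def test_identical_estimates_give_normal_interval(self):
        fits = [
            FitResult(np.array([1.0, 1.0, 1.0]), np.array([0.5, 0.5, 0.5]), True, LOG_BINOMIAL, 10)
            for _ in range(5)
        ]
        pooled = pool_rubin(fits)
        assert pooled.total_variance[0] == pytest.approx(0.25)  # B=0 -> T=W
        assert np.all(np.isinf(pooled.dof))
        assert pooled.ci_high[0] - pooled.estimates[0] == pytest.approx(1.96 * 0.5, abs=1e-3)

    def test_order_invariance_and_total_dominates_within(self, rng):
        fits = [
            FitResult(rng.normal(size=3), np.abs(rng.normal(size=3)) + 0.1, True, LOG_BINOMIAL, 10)
            for _ in range(8)
        ]
        a = pool_rubin(fits)
        b = pool_rubin(fits[::-1])
        np.testing.assert_allclose(a.estimates, b.estimates)
        np.testing.assert_allclose(a.total_variance, b.total_variance)
        W = np.mean([f.std_errors**2 for f in fits], axis=0)
        assert np.all(a.total_variance >= W)
        assert np.all(a.ci_low < a.ci_high)

    @settings(derandomize=True, max_examples=60)
    @given(
        ests=st.lists(
            st.floats(min_value=-5.0, max_value=5.0), min_size=2, max_size=12
        ),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_pooling_invariants_hold_for_arbitrary_inputs(self, ests, seed):
        # T >= W with equality iff B = 0; intervals are ordered; pooled
        # estimate is the plain mean
        rng = np.random.default_rng(seed)
        ses = rng.uniform(0.05, 2.0, size=(len(ests), 3))
        fits = [
            FitResult(np.full(3, e), s, True, LOG_BINOMIAL, 10)
            for e, s in zip(ests, ses)
        ]
        pooled = pool_rubin(fits)
        W = (ses**2).mean(axis=0)
        B = np.var(ests, ddof=1)
        assert np.all(pooled.total_variance >= W - 1e-12)
        if B == 0.0:
            np.testing.assert_allclose(pooled.total_variance, W)
        assert np.all(pooled.ci_low < pooled.ci_high)
        assert pooled.estimates[0] == pytest.approx(np.mean(ests))

    def test_fewer_than_two_fits_rejected(self):
        f = FitResult(np.zeros(3), np.ones(3), True, LOG_BINOMIAL, 10)
        with pytest.raises(ValueError):
            pool_rubin([f])


class TestDeletionAndCCA:
    def _imp(self, rng, n=60, miss_frac=0.3):
        miss_y = rng.random(n) < miss_frac
        miss_x2 = rng.random(n) < miss_frac
        completed = [
            _dataset(
                (rng.random(n) < 0.4).astype(float),
                (rng.random(n) < 0.5).astype(float),
                (rng.random(n) < 0.5).astype(float),
            )
            for _ in range(3)
        ]
        return ImputationSet(completed, miss_y, "FCS"), miss_y, miss_x2

    def test_no_imputed_outcomes_is_identity(self, rng):
        imp, _, _ = self._imp(rng, miss_frac=0.0)
        out = delete_imputed_outcomes(imp)
        assert all(d.n == 60 for d in out.completed)
        np.testing.assert_array_equal(out.completed[0].y, imp.completed[0].y)

    def test_rows_with_imputed_y_removed_exactly(self, rng):
        imp, miss_y, _ = self._imp(rng)
        out = delete_imputed_outcomes(imp)
        expected = 60 - int(miss_y.sum())
        assert all(d.n == expected for d in out.completed)
        np.testing.assert_array_equal(
            out.completed[1].x2, imp.completed[1].x2[~miss_y]
        )  # imputed covariates in retained rows kept

    def test_cca_drops_incomplete_rows(self, rng):
        ds = _simulate(rng, n=600)
        full = choose_analysis(ds, "binary")
        assert np.allclose(cca_fit(ds, "binary").estimates, full.estimates)
        ds2 = _dataset(ds.y, ds.x1, ds.x2, rng.random(600) < 0.3, rng.random(600) < 0.3)
        fit = cca_fit(ds2, "binary")
        assert fit.n_used == int(ds2.complete_rows.sum())

    def test_cca_too_few_rows_flagged(self, rng):
        ds = _simulate(rng, n=20)
        ds.miss_y[:15] = True
        ds.miss_x2[:] = True
        with pytest.raises(FitError):
            cca_fit(ds, "binary")
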