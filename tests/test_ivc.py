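"""Instrumental-variable calibration: slopes, weights, totals, variances."""

import numpy as np
import pytest

from ivcalib.calibration import chisq_calibration_weights, greg_total
from ivcalib.dgp import DGPConfig, generate_population
from ivcalib.design import draw_srswor
from ivcalib.exceptions import (
    NotSupportedError,
    SingularDesignError,
    UndefinedVarianceError,
    WeakInstrumentError,
)
from ivcalib.ivc import (
    beta_iv,
    beta_ols,
    ivc_asymptotic_variance,
    ivc_population_variance,
    ivc_total,
    ivc_weights,
    mbivc_mse,
    mbivc_total,
    mbivc_weights,
)
from tests.conftest import make_srswor_sample, random_instance


class TestSlopes:
    def test_ols_exact_line_through_origin(self):
        res = beta_ols(np.array([[1.0], [2.0], [3.0]]), np.array([2.0, 4.0, 6.0]))
        assert res.beta == pytest.approx([2.0])
        assert res.method == "OLS"

    def test_ols_recovers_exact_linear_coefficients(self, rng):
        X = rng.normal(size=(20, 3))
        c = np.array([1.5, -2.0, 0.25])
        assert beta_ols(X, X @ c).beta == pytest.approx(c, rel=1e-10)

    def test_ols_matches_direct_minimization(self, rng):
        # independent oracle: minimize ||y - Xb||^2 numerically
        from scipy.optimize import minimize

        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(size=20)
        direct = minimize(
            lambda b: np.sum((y - X @ b) ** 2), np.zeros(3), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000},
        )
        assert beta_ols(X, y).beta == pytest.approx(direct.x, abs=1e-5)

    def test_ols_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(30, 4))
        y = X @ np.ones(4) + rng.normal(size=30)
        assert beta_ols(X, y).beta == pytest.approx(sm.OLS(y, X).fit().params, rel=1e-10)

    def test_ols_rank_deficiency_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        X[:, 1] = 2 * X[:, 0]
        with pytest.raises(SingularDesignError):
            beta_ols(X, rng.normal(size=10))

    def test_iv_collapses_to_ols_with_own_instruments(self, rng):
        X = rng.normal(size=(25, 3))
        y = X @ np.ones(3) + rng.normal(size=25)
        assert beta_iv(X, X, y).beta == pytest.approx(beta_ols(X, y).beta, rel=1e-10)

    def test_iv_zero_residual_recovers_coefficients(self, rng):
        X = rng.normal(size=(25, 2))
        Z = X.copy()
        Z[:, 0] = X[:, 0] + 0.5 * rng.normal(size=25)
        c = np.array([3.0, -1.0])
        assert beta_iv(X, Z, X @ c).beta == pytest.approx(c, rel=1e-10)

    def test_iv_matches_statsmodels_2sls_under_exact_identification(self, rng):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        X = rng.normal(size=(40, 3))
        Z = X.copy()
        Z[:, 1] = X[:, 1] + rng.normal(size=40)
        y = X @ np.ones(3) + rng.normal(size=40)
        oracle = IV2SLS(y, X, instrument=Z).fit().params
        assert beta_iv(X, Z, y).beta == pytest.approx(oracle, rel=1e-10)

    def test_over_identification_not_supported(self, rng):
        X = rng.normal(size=(20, 2))
        Z = rng.normal(size=(20, 3))
        with pytest.raises(NotSupportedError):
            beta_iv(X, Z, rng.normal(size=20))

    def test_irrelevant_instrument_raises_weak_instrument(self, rng):
        X = rng.normal(size=(20, 2))
        Z = X.copy()
        Z[:, 0] = 0.0  # no relevance at all -> singular Z'X
        with pytest.raises(WeakInstrumentError) as exc:
            beta_iv(X, Z, rng.normal(size=20))
        assert exc.value.rcond is not None

    def test_iv_consistent_under_endogeneity_where_ols_is_not(self):
        # large synthetic population: the IV slope sits at the true value
        # while OLS is shifted by gamma sigma_e^2 / Var(x_endog) = 1/3
        pop = generate_population(DGPConfig(N=60_000, p=3, seed=11))
        iv = beta_iv(pop.X, pop.Z, pop.y).beta
        ols = beta_ols(pop.X, pop.y).beta
        assert abs(iv[0] - 1.0) < 0.05
        assert ols[0] - 1.0 == pytest.approx(1.0 / 3.0, rel=0.15)


class TestIvcWeights:
    def test_reduces_to_chisq_weights_with_own_instruments(self, rng):
        s, X, _, t_x = random_instance(rng, n=12, p=3, endog=None)
        assert np.allclose(
            ivc_weights(s, X, X, t_x).w,
            chisq_calibration_weights(s, X, t_x).w,
            atol=1e-10,
        )

    def test_presatisfied_constraints_leave_design_weights(self, rng):
        s, X, Z, _ = random_instance(rng, n=10, p=2)
        res = ivc_weights(s, X, Z, X.T @ s.d)
        assert np.allclose(res.w, s.d, atol=1e-10)

    def test_calibrates_on_x_not_z_and_differs_from_chisq(self, rng):
        s, X, Z, t_x = random_instance(rng, n=10, p=2)
        res = ivc_weights(s, X, Z, t_x)
        assert np.allclose(X.T @ res.w, t_x, rtol=1e-10)
        assert not np.allclose(res.w, chisq_calibration_weights(s, X, t_x).w)
        # and the Z-side equations are NOT enforced
        assert not np.allclose(Z.T @ res.w, t_x, rtol=1e-6)

    def test_weak_instrument_guard(self, rng):
        s, X, Z, t_x = random_instance(rng, n=10, p=2)
        Z[:, 0] = 0.0
        with pytest.raises(WeakInstrumentError):
            ivc_weights(s, X, Z, t_x)


class TestIvcTotal:
    def test_equals_greg_with_own_instruments(self, rng):
        s, X, _, t_x = random_instance(rng, n=12, p=3, endog=None)
        y = rng.normal(size=12)
        assert ivc_total(s, y, X, X, t_x).estimate == pytest.approx(
            greg_total(s, y, X, t_x).estimate, rel=1e-10
        )

    def test_zero_residual_exactness_any_instruments(self, rng):
        s, X, Z, t_x = random_instance(rng, n=10, p=2)
        c = np.array([1.0, -2.0])
        assert ivc_total(s, X @ c, X, Z, t_x).estimate == pytest.approx(
            t_x @ c, rel=1e-10
        )

    def test_weight_and_regression_paths_agree_on_tiny_instance(self, rng):
        s, X, Z, t_x = random_instance(rng, n=4, p=2)
        y = rng.normal(size=4)
        res = ivc_total(s, y, X, Z, t_x)
        w = ivc_weights(s, X, Z, t_x).w
        assert res.estimate == pytest.approx(float(w @ y), rel=1e-10)
        assert res.beta.shape == (2,)


class TestIvcVariance:
    def test_zero_residuals_give_zero_variance(self, rng):
        s, X, Z, t_x = random_instance(rng, n=8, p=2)
        c = np.array([2.0, 1.0])
        assert ivc_asymptotic_variance(s, X @ c, X, Z, t_x) == pytest.approx(0.0, abs=1e-16)

    def test_census_variance_vanishes(self, rng):
        n = 8
        s = make_srswor_sample(N=n, n=n)
        X = rng.normal(size=(n, 2))
        Z = X.copy()
        y = rng.normal(size=n)
        assert ivc_asymptotic_variance(s, y, X, Z, X.T @ s.d) == 0.0

    def test_single_unit_rejected(self, rng):
        s = make_srswor_sample(N=10, n=1)
        with pytest.raises(UndefinedVarianceError):
            ivc_asymptotic_variance(s, np.ones(1), np.ones((1, 1)), np.ones((1, 1)),
                                    np.ones(1))

    def test_population_evaluator_matches_closed_form(self, rng):
        pop = generate_population(DGPConfig(N=200, p=2, seed=3))
        beta = np.ones(2)
        E = pop.y - pop.X @ beta
        n = 50
        expected = 200**2 * (1 - n / 200) * np.var(E, ddof=1) / n
        assert ivc_population_variance(pop, n, beta) == pytest.approx(expected, rel=1e-12)


class TestMbivc:
    def test_census_weights_are_all_one(self, rng):
        X = rng.normal(size=(6, 2))
        Z = X.copy()
        res = mbivc_weights(X, Z, np.zeros(2))
        assert np.allclose(res.w, 1.0)

    def test_reduces_to_projection_weights_with_own_instruments(self, rng):
        X = rng.normal(size=(8, 2))
        t_ns = rng.normal(size=2) * 5
        res = mbivc_weights(X, X, t_ns)
        proj = 1.0 + X @ np.linalg.solve(X.T @ X, t_ns)
        assert np.allclose(res.w, proj, atol=1e-10)

    def test_calibration_constraint_holds(self, rng):
        X = rng.normal(size=(6, 2))
        Z = X.copy()
        Z[:, 1] = X[:, 1] + 0.5 * rng.normal(size=6)
        t_ns = rng.normal(size=2) * 4
        res = mbivc_weights(X, Z, t_ns)
        assert np.allclose(X.T @ res.w, t_ns + X.sum(axis=0), rtol=1e-10)

    def test_total_census_equals_true_total(self, rng):
        pop = generate_population(DGPConfig(N=30, p=2, seed=5))
        res = mbivc_total(pop.y, pop.X, pop.Z, np.zeros(2))
        assert res.estimate == pytest.approx(pop.t_y, rel=1e-12)

    def test_zero_residual_exactness(self, rng):
        X = rng.normal(size=(8, 2))
        Z = X.copy()
        Z[:, 0] = X[:, 0] + rng.normal(size=8)
        c = np.array([1.0, 2.0])
        t_ns = rng.normal(size=2) * 3
        res = mbivc_total(X @ c, X, Z, t_ns)
        assert res.estimate == pytest.approx((t_ns + X.sum(axis=0)) @ c, rel=1e-10)

    def test_weight_and_regression_paths_agree(self, rng):
        X = rng.normal(size=(7, 2))
        Z = X.copy()
        Z[:, 0] = X[:, 0] + 0.3 * rng.normal(size=7)
        y = rng.normal(size=7)
        t_ns = rng.normal(size=2) * 2
        res = mbivc_total(y, X, Z, t_ns)
        w = mbivc_weights(X, Z, t_ns).w
        assert res.estimate == pytest.approx(float(w @ y), rel=1e-10)

    def test_mse_zero_for_perfect_fit_and_census(self, rng):
        X = rng.normal(size=(8, 2))
        Z = X.copy()
        c = np.array([1.0, -1.0])
        assert mbivc_mse(X @ c, X, Z, np.ones(2)) == pytest.approx(0.0, abs=1e-18)
        assert mbivc_mse(rng.normal(size=8), X, Z, np.zeros(2)) == 0.0

    def test_mse_nonnegative_and_respects_reference_slope(self, rng):
        X = rng.normal(size=(10, 2))
        Z = X.copy()
        Z[:, 0] = X[:, 0] + rng.normal(size=10)
        y = X @ np.ones(2) + rng.normal(size=10)
        t_ns = rng.normal(size=2) * 5
        default = mbivc_mse(y, X, Z, t_ns)
        referenced = mbivc_mse(y, X, Z, t_ns, beta_ref=np.zeros(2))
        assert default >= 0.0
        assert referenced >= 0.0
        assert referenced != pytest.approx(default)


def test_slope_recovery_under_endogeneity_vs_calibration_slope():
    """With a large sample from an endogenous population, the IVC slope
    recovers beta = 1 while the GREG (chi-square) slope stays shifted."""
    pop = generate_population(DGPConfig(N=20_000, p=4, seed=21))
    rng = np.random.default_rng(77)
    sample = draw_srswor(pop, 5000, rng)
    y_s, X_s, Z_s = (sample.restrict(a) for a in (pop.y, pop.X, pop.Z))
    ivc = ivc_total(sample, y_s, X_s, Z_s, pop.t_x)
    greg = greg_total(sample, y_s, X_s, pop.t_x)
    assert abs(ivc.beta[0] - 1.0) < 0.1
    assert greg.beta[0] - 1.0 == pytest.approx(1.0 / 3.0, abs=0.12)
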