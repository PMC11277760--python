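"""Instrumental-variable calibration (IVC) estimators of a population total.

When an auxiliary variable x_j is endogenous — correlated with the
error of the working model y = X beta + e — the regression slope
implicit in calibration/GREG is inconsistent, and so is the efficiency
rationale of the weights.  The classical remedy is an instrument z_j,
correlated with x_j but not with e; under exact identification the
instrument matrix Z has the same shape as X (exogenous columns act as
their own instruments) and the IV slope is

    beta_IV = (Z'X)^{-1} Z'y.

Two estimator families are implemented:

* model-assisted (design-based) IVC: weights
  ``W = d + PiInv Z_s (Z_s' PiInv X_s)^{-1} (t_x - X_s' d)`` with
  PiInv = diag(q_k d_k).  They calibrate exactly on X (not on Z), and
  the total can equivalently be written
  ``t_IVC = t_HT + (t_x - t_x_HT)' beta_IVC`` with
  beta_IVC = (Z_s' PiInv X_s)^{-1} Z_s' PiInv y_s.

* model-based IVC (MBIVC): weights ``W = 1 + Z_s (Z_s'X_s)^{-T} t_x_ns``
  where t_x_ns are the X totals over the non-sampled units; the total is
  ``t_MBIVC = sum_s y_k + t_x_ns' beta_MBIVC`` with
  beta_MBIVC = (Z_s'X_s)^{-1} Z_s' y_s.

Both families reduce exactly to their classical counterparts (chi-square
calibration / model-based projection) when Z = X.  Every cross-Gram
solve is guarded: a reciprocal condition number below 1e-12 raises a
weak-instrument error instead of returning explosive weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import reciprocal_condition, solve_checked
from .calibration import CalibrationWeights, constraint_gap
from .design import FinitePopulation, SurveySample, TotalEstimate
from .exceptions import (
    AlignmentError,
    NotSupportedError,
    SingularDesignError,
    UndefinedVarianceError,
    WeakInstrumentError,
)

__all__ = [
    "SlopeEstimate",
    "beta_ols",
    "beta_iv",
    "ivc_weights",
    "ivc_total",
    "ivc_asymptotic_variance",
    "ivc_population_variance",
    "mbivc_weights",
    "mbivc_total",
    "mbivc_mse",
]


@dataclass(frozen=True)
class SlopeEstimate:
    """A regression slope with its provenance and conditioning."""

    beta: np.ndarray
    method: str
    gram_condition: float


def _as_2d(M, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if M.ndim != 2:
        raise AlignmentError(f"{name} must be a 2-d matrix")
    return M


def _check_exact_identification(X: np.ndarray, Z: np.ndarray) -> None:
    if Z.shape != X.shape:
        raise NotSupportedError(
            "exact identification requires Z with the same shape as X "
            f"(got X {X.shape}, Z {Z.shape}); over-identification is not supported"
        )


def beta_ols(X: np.ndarray, y: np.ndarray) -> SlopeEstimate:
    """Ordinary least squares slope (X'X)^{-1} X'y."""
    X = _as_2d(X, "X")
    y = np.asarray(y, dtype=float).ravel()
    m, p = X.shape
    if y.shape[0] != m:
        raise AlignmentError("y length does not match rows of X")
    if m < p:
        raise SingularDesignError(f"need at least p={p} rows, got {m}")
    gram = X.T @ X
    beta = solve_checked(gram, X.T @ y, SingularDesignError, "Gram matrix X'X")
    return SlopeEstimate(beta=beta, method="OLS", gram_condition=reciprocal_condition(gram))


def beta_iv(X: np.ndarray, Z: np.ndarray, y: np.ndarray) -> SlopeEstimate:
    """Instrumental-variable slope (Z'X)^{-1} Z'y under exact identification."""
    X = _as_2d(X, "X")
    Z = _as_2d(Z, "Z")
    _check_exact_identification(X, Z)
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != X.shape[0]:
        raise AlignmentError("y length does not match rows of X")
    cross = Z.T @ X
    beta = solve_checked(cross, Z.T @ y, WeakInstrumentError, "cross-Gram Z'X")
    return SlopeEstimate(beta=beta, method="IV", gram_condition=reciprocal_condition(cross))


def _sample_arrays(sample: SurveySample, X_s, Z_s, t_x):
    X_s = _as_2d(X_s, "X_s")
    Z_s = _as_2d(Z_s, "Z_s")
    _check_exact_identification(X_s, Z_s)
    t_x = np.asarray(t_x, dtype=float).ravel()
    if X_s.shape[0] != sample.n:
        raise AlignmentError(f"X_s has {X_s.shape[0]} rows, sample has n={sample.n}")
    if t_x.shape[0] != X_s.shape[1]:
        raise AlignmentError("t_x length does not match columns of X_s")
    return X_s, Z_s, t_x


def ivc_weights(
    sample: SurveySample, X_s: np.ndarray, Z_s: np.ndarray, t_x: np.ndarray
) -> CalibrationWeights:
    """Model-assisted IVC weights; calibrate exactly on X, built from Z."""
    X_s, Z_s, t_x = _sample_arrays(sample, X_s, Z_s, t_x)
    qd = sample.q * sample.d
    cross = Z_s.T @ (qd[:, None] * X_s)
    # W = d + PiInv Z mu must satisfy X'W = t_x, so mu solves against
    # X'PiInv Z = (Z'PiInv X)'; the cross-Gram is not symmetric when Z != X.
    lam = solve_checked(
        cross.T, t_x - X_s.T @ sample.d, WeakInstrumentError, "cross-Gram Z'PiInv X"
    )
    w = sample.d + qd * (Z_s @ lam)
    return CalibrationWeights(
        w=w,
        lam=lam,
        method="ivc",
        converged=True,
        n_iter=1,
        constraint_gap=constraint_gap(w, X_s, t_x),
    )


def _beta_ivc(sample: SurveySample, X_s, Z_s, y_s) -> np.ndarray:
    qd = sample.q * sample.d
    cross = Z_s.T @ (qd[:, None] * X_s)
    return solve_checked(
        cross, Z_s.T @ (qd * y_s), WeakInstrumentError, "cross-Gram Z'PiInv X"
    )


def ivc_total(
    sample: SurveySample,
    y_s: np.ndarray,
    X_s: np.ndarray,
    Z_s: np.ndarray,
    t_x: np.ndarray,
) -> TotalEstimate:
    """Model-assisted IVC estimator of the total.

    Regression form ``t_HT + (t_x - t_x_HT)' beta_IVC``; cross-checked
    against the weight form ``sum_s W_k y_k`` at 1e-8 relative.
    """
    X_s, Z_s, t_x = _sample_arrays(sample, X_s, Z_s, t_x)
    y_s = np.asarray(y_s, dtype=float).ravel()
    if y_s.shape[0] != sample.n:
        raise AlignmentError("y_s length does not match the sample size")
    beta = _beta_ivc(sample, X_s, Z_s, y_s)
    estimate = float(sample.d @ y_s) + float(beta @ (t_x - X_s.T @ sample.d))

    est_w = float(ivc_weights(sample, X_s, Z_s, t_x).w @ y_s)
    if abs(estimate - est_w) > 1e-8 * max(1.0, abs(estimate)):
        raise AssertionError(
            f"IVC regression and weight paths disagree: {estimate!r} vs {est_w!r}"
        )
    return TotalEstimate(estimate=estimate, estimator="IVC", beta=beta)


def ivc_asymptotic_variance(
    sample: SurveySample,
    y_s: np.ndarray,
    X_s: np.ndarray,
    Z_s: np.ndarray,
    t_x: np.ndarray,
) -> float:
    """Plug-in asymptotic variance of the IVC total under SRSWOR.

    The asymptotic variance is the design double sum over
    Delta_kl with the IV residuals y_k - x_k' beta in place of y;
    specialised to SRSWOR and estimated with sample residuals
    e_k = y_k - x_k' beta_IVC this is ``N^2 (1 - n/N) s^2_e / n``.
    """
    X_s, Z_s, t_x = _sample_arrays(sample, X_s, Z_s, t_x)
    y_s = np.asarray(y_s, dtype=float).ravel()
    n, N = sample.n, sample.N
    if n < 2:
        raise UndefinedVarianceError("variance estimation needs n >= 2")
    beta = _beta_ivc(sample, X_s, Z_s, y_s)
    e = y_s - X_s @ beta
    return N**2 * (1.0 - n / N) * float(np.var(e, ddof=1)) / n


def ivc_population_variance(
    population: FinitePopulation, n: int, beta: np.ndarray
) -> float:
    """Theoretical SRSWOR design variance of the IVC total at a given slope.

    Evaluates the population-level double-sum form
    ``N^2 (1 - n/N) S^2_E / n`` with E_k = y_k - x_k' beta and S^2_E the
    population variance (denominator N-1).  Used as an oracle against
    the plug-in estimator; not estimable from a sample.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    E = population.y - population.X @ beta
    N = population.N
    if not 1 <= n <= N:
        raise UndefinedVarianceError(f"sample size {n} outside [1, {N}]")
    return N**2 * (1.0 - n / N) * float(np.var(E, ddof=1)) / n


def _mbivc_arrays(X_s, Z_s, t_x_nonsample):
    X_s = _as_2d(X_s, "X_s")
    Z_s = _as_2d(Z_s, "Z_s")
    _check_exact_identification(X_s, Z_s)
    t_ns = np.asarray(t_x_nonsample, dtype=float).ravel()
    if t_ns.shape[0] != X_s.shape[1]:
        raise AlignmentError("t_x_nonsample length does not match columns of X_s")
    return X_s, Z_s, t_ns


def mbivc_weights(
    X_s: np.ndarray, Z_s: np.ndarray, t_x_nonsample: np.ndarray
) -> CalibrationWeights:
    """Model-based IVC weights ``W_k = 1 + t_x_ns' (Z_s'X_s)^{-1} z_k``.

    ``t_x_nonsample`` is the vector of X column totals over the
    non-sampled units, t_x - sum_s x_k.  The weights calibrate exactly:
    sum_s W_k x_k = t_x.
    """
    X_s, Z_s, t_ns = _mbivc_arrays(X_s, Z_s, t_x_nonsample)
    cross = Z_s.T @ X_s
    lam = solve_checked(cross.T, t_ns, WeakInstrumentError, "cross-Gram Z'X")
    w = 1.0 + Z_s @ lam
    t_x = t_ns + X_s.sum(axis=0)
    return CalibrationWeights(
        w=w,
        lam=lam,
        method="mbivc",
        converged=True,
        n_iter=1,
        constraint_gap=constraint_gap(w, X_s, t_x),
    )


def mbivc_total(
    y_s: np.ndarray,
    X_s: np.ndarray,
    Z_s: np.ndarray,
    t_x_nonsample: np.ndarray,
) -> TotalEstimate:
    """Model-based IVC estimator ``sum_s y_k + t_x_ns' beta_MBIVC``."""
    X_s, Z_s, t_ns = _mbivc_arrays(X_s, Z_s, t_x_nonsample)
    y_s = np.asarray(y_s, dtype=float).ravel()
    if y_s.shape[0] != X_s.shape[0]:
        raise AlignmentError("y_s length does not match rows of X_s")
    cross = Z_s.T @ X_s
    beta = solve_checked(cross, Z_s.T @ y_s, WeakInstrumentError, "cross-Gram Z'X")
    estimate = float(y_s.sum()) + float(t_ns @ beta)

    est_w = float(mbivc_weights(X_s, Z_s, t_ns).w @ y_s)
    if abs(estimate - est_w) > 1e-8 * max(1.0, abs(estimate)):
        raise AssertionError(
            f"MBIVC regression and weight paths disagree: {estimate!r} vs {est_w!r}"
        )
    return TotalEstimate(estimate=estimate, estimator="MBIVC", beta=beta)


def mbivc_mse(
    y_s: np.ndarray,
    X_s: np.ndarray,
    Z_s: np.ndarray,
    t_x_nonsample: np.ndarray,
    beta_ref: np.ndarray | None = None,
) -> float:
    """Sandwich estimate of the slope-error contribution to the MBIVC MSE.

    Returns ``t_x_ns' A^{-1} M A^{-T} t_x_ns`` with A = Z_s'X_s and
    M = sum_s r_k^2 z_k z_k', r_k = y_k - x_k' beta_ref.  The reference
    slope defaults to beta_MBIVC, which makes the quantity computable
    from the sample alone; pass the (super)population slope to evaluate
    the theoretical form.  Nonnegative by construction.
    """
    X_s, Z_s, t_ns = _mbivc_arrays(X_s, Z_s, t_x_nonsample)
    y_s = np.asarray(y_s, dtype=float).ravel()
    cross = Z_s.T @ X_s
    if beta_ref is None:
        beta_ref = solve_checked(cross, Z_s.T @ y_s, WeakInstrumentError, "cross-Gram Z'X")
    else:
        beta_ref = np.asarray(beta_ref, dtype=float).ravel()
    r = y_s - X_s @ beta_ref
    v = solve_checked(cross.T, t_ns, WeakInstrumentError, "cross-Gram Z'X")
    M = (Z_s * (r**2)[:, None]).T @ Z_s
    return float(v @ M @ v)
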