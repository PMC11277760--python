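"""Classical calibration weighting and the GREG estimator.

Calibration adjusts the design weights d_k as little as possible (per a
distance function) subject to the calibration equations

    sum_s w_k x_k = t_x,

so the weighted sample totals of the p auxiliary variables reproduce
their known population totals exactly.  With the chi-square distance
``sum_s (w_k - d_k)^2 / (q_k d_k)`` the solution is available in closed
form, ``w_k = d_k (1 + q_k x_k' lam)``, and the resulting estimator of
t_y is algebraically the generalized regression (GREG) estimator

    t_GREG = t_HT + b_s' (t_x - t_x_HT),
    b_s = (sum_s d_k q_k x_k x_k')^{-1} sum_s d_k q_k x_k y_k.

For a general distance, w_k = d_k F(q_k x_k' lam) and lam solves the
calibration equations by Newton's method; F(u) = 1 + u (chi-square,
one Newton step is exact) and F(u) = exp(u) (raking) are provided.

Chi-square weights can be negative; they are deliberately not clipped
or bounded here — bounded-distance calibration is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import solve_checked
from .design import SurveySample, TotalEstimate
from .exceptions import AlignmentError, SingularDesignError

__all__ = [
    "CalibrationWeights",
    "chisq_calibration_weights",
    "newton_calibration_weights",
    "greg_total",
]

#: Newton defaults: chi-square converges in one step, raking typically < 10.
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 50


@dataclass(frozen=True)
class CalibrationWeights:
    """Final unit weights with the Lagrange multiplier and diagnostics.

    ``constraint_gap`` is the maximum relative violation of the
    calibration equations, max_j |sum_s w_k x_kj - t_xj| / max(|t_xj|, 1).
    """

    w: np.ndarray
    lam: np.ndarray
    method: str
    converged: bool
    n_iter: int
    constraint_gap: float


def constraint_gap(w: np.ndarray, X_s: np.ndarray, t_x: np.ndarray) -> float:
    """Max relative violation of the calibration equations on X."""
    achieved = X_s.T @ w
    denom = np.maximum(np.abs(t_x), 1.0)
    return float(np.max(np.abs(achieved - t_x) / denom))


def _validate(sample: SurveySample, X_s: np.ndarray, t_x: np.ndarray):
    X_s = np.atleast_2d(np.asarray(X_s, dtype=float))
    t_x = np.asarray(t_x, dtype=float).ravel()
    if X_s.shape[0] != sample.n:
        raise AlignmentError(
            f"X_s has {X_s.shape[0]} rows but the sample has n={sample.n}"
        )
    if X_s.shape[1] != t_x.shape[0]:
        raise AlignmentError(
            f"t_x has length {t_x.shape[0]} but X_s has {X_s.shape[1]} columns"
        )
    return X_s, t_x


def chisq_calibration_weights(
    sample: SurveySample, X_s: np.ndarray, t_x: np.ndarray
) -> CalibrationWeights:
    """Closed-form chi-square calibration weights.

    Solves lam from the p-by-p Gram system
    ``(sum_s d_k q_k x_k x_k') lam = t_x - t_x_HT`` and returns
    ``w = d + diag(q d) X_s lam``.  The calibration equations then hold
    to machine precision.
    """
    X_s, t_x = _validate(sample, X_s, t_x)
    qd = sample.q * sample.d
    gram = X_s.T @ (qd[:, None] * X_s)
    resid = t_x - X_s.T @ sample.d
    lam = solve_checked(gram, resid, SingularDesignError, "auxiliary Gram matrix X'PiInv X")
    w = sample.d + qd * (X_s @ lam)
    return CalibrationWeights(
        w=w,
        lam=lam,
        method="chisq_closed_form",
        converged=True,
        n_iter=1,
        constraint_gap=constraint_gap(w, X_s, t_x),
    )


_DISTANCES = {
    # F(u), F'(u) for w_k = d_k F(q_k x_k' lam)
    "chisq": (lambda u: 1.0 + u, lambda u: np.ones_like(u)),
    "raking": (np.exp, np.exp),
}


def newton_calibration_weights(
    sample: SurveySample,
    X_s: np.ndarray,
    t_x: np.ndarray,
    distance: str = "chisq",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CalibrationWeights:
    """Calibration weights for a general distance via Newton iteration.

    Iterates ``lam <- lam + J(lam)^{-1} (t_x - sum_s w_k(lam) x_k)``
    with Jacobian ``J = sum_s d_k q_k F'(u_k) x_k x_k'`` starting from
    lam = 0, stopping when the max relative constraint gap falls below
    ``tol``.  Non-convergence within ``max_iter`` returns the last
    iterate with ``converged=False`` rather than raising.
    """
    if distance not in _DISTANCES:
        raise ValueError(f"unknown distance {distance!r}; choose from {sorted(_DISTANCES)}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    X_s, t_x = _validate(sample, X_s, t_x)
    F, dF = _DISTANCES[distance]
    qd = sample.q * sample.d

    lam = np.zeros(t_x.shape[0])
    w = sample.d.copy()  # F(0) = 1 for both families
    gap = constraint_gap(w, X_s, t_x)
    n_iter = 0
    while gap > tol and n_iter < max_iter:
        u = sample.q * (X_s @ lam)
        jac = X_s.T @ ((qd * dF(u))[:, None] * X_s)
        resid = t_x - X_s.T @ (sample.d * F(u))
        lam = lam + solve_checked(
            jac, resid, SingularDesignError, "calibration Jacobian"
        )
        n_iter += 1
        w = sample.d * F(sample.q * (X_s @ lam))
        gap = constraint_gap(w, X_s, t_x)
    return CalibrationWeights(
        w=w,
        lam=lam,
        method=f"newton_{distance}",
        converged=bool(gap <= tol),
        n_iter=n_iter,
        constraint_gap=gap,
    )


def greg_total(
    sample: SurveySample, y_s: np.ndarray, X_s: np.ndarray, t_x: np.ndarray
) -> TotalEstimate:
    """Generalized regression (GREG) estimator of the total.

    Computes both the regression form ``t_HT + b_s'(t_x - t_x_HT)`` and
    the weight form ``sum_s w_k y_k`` from the chi-square weights; the
    two are algebraically identical and are cross-checked at 1e-8
    relative before returning.
    """
    X_s, t_x = _validate(sample, X_s, t_x)
    y_s = np.asarray(y_s, dtype=float).ravel()
    if y_s.shape[0] != sample.n:
        raise AlignmentError("y_s length does not match the sample size")
    qd = sample.q * sample.d
    gram = X_s.T @ (qd[:, None] * X_s)
    b_s = solve_checked(
        gram, X_s.T @ (qd * y_s), SingularDesignError, "auxiliary Gram matrix X'PiInv X"
    )
    t_ht = float(sample.d @ y_s)
    estimate = t_ht + float(b_s @ (t_x - X_s.T @ sample.d))

    weights = chisq_calibration_weights(sample, X_s, t_x)
    est_w = float(weights.w @ y_s)
    scale = max(1.0, abs(estimate))
    if abs(estimate - est_w) > 1e-8 * scale:
        raise AssertionError(
            "GREG regression and weight paths disagree: "
            f"{estimate!r} vs {est_w!r}"
        )
    return TotalEstimate(estimate=estimate, estimator="GREG", beta=b_s)
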