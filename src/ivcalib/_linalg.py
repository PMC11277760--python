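"""Guarded linear solves shared by the calibration estimators.

All (.)^{-1} expressions in the estimator algebra are evaluated through a
pivoted LU solve, never an explicit inverse.  Before solving, the
reciprocal condition number of the matrix is measured by SVD; anything
below ``RCOND_MIN`` raises a typed error naming the columns implicated
in the near-null space (largest components of the right singular vector
belonging to the smallest singular value).
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

RCOND_MIN = 1e-12


def reciprocal_condition(A: np.ndarray) -> float:
    """Smallest-over-largest singular value of a square matrix."""
    s = np.linalg.svd(np.asarray(A, dtype=float), compute_uv=False)
    if s[0] == 0.0:
        return 0.0
    return float(s[-1] / s[0])


def _offending_columns(A: np.ndarray) -> tuple[int, ...]:
    # columns with dominant weight in the near-null right singular vector
    _, _, vt = np.linalg.svd(np.asarray(A, dtype=float))
    v = np.abs(vt[-1])
    thresh = max(0.5 * v.max(), 1.0 / (2.0 * np.sqrt(len(v))))
    return tuple(int(j) for j in np.nonzero(v >= thresh)[0])


def solve_checked(A: np.ndarray, b: np.ndarray, error_cls, what: str):
    """Solve ``A x = b`` with a pivoted factorization, guarding rank.

    Parameters
    ----------
    A : square matrix to invert against.
    b : right-hand side (vector or matrix).
    error_cls : exception class raised on near-singularity
        (``SingularDesignError`` or ``WeakInstrumentError``).
    what : human-readable name of the matrix for the error message.
    """
    A = np.asarray(A, dtype=float)
    rcond = reciprocal_condition(A)
    if rcond < RCOND_MIN:
        cols = _offending_columns(A)
        raise error_cls(
            f"{what} is numerically singular (reciprocal condition number "
            f"{rcond:.3e} < {RCOND_MIN:g}); columns involved: {list(cols)}",
            columns=cols,
            rcond=rcond,
        )
    return scipy.linalg.solve(A, np.asarray(b, dtype=float))
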