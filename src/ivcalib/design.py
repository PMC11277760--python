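"""Finite-population bookkeeping, SRSWOR draws and the Horvitz-Thompson estimator.

The estimand throughout the package is the finite-population total
``t_y = sum_U y_k`` of a study variable over a universe U of N units.
A probability sample s with first-order inclusion probabilities pi_k
yields the design weights ``d_k = 1/pi_k`` and the Horvitz-Thompson (HT)
estimator ``t_hat = sum_s d_k y_k``.  Only simple random sampling
without replacement (SRSWOR) is implemented as a design: every size-n
subset is equally likely, so pi_k = n/N for every unit and the joint
inclusion probability is pi_kl = n(n-1)/(N(N-1)), which lets the
Sen-Yates-Grundy double sum collapse to the familiar closed form
``N^2 (1 - n/N) s^2_y / n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator

import numpy as np

from .exceptions import (
    AlignmentError,
    ConfigError,
    InvalidSampleSizeError,
    UndefinedVarianceError,
)

__all__ = [
    "FinitePopulation",
    "SurveySample",
    "TotalEstimate",
    "draw_srswor",
    "all_srswor_samples",
    "ht_total",
    "ht_variance",
]


@dataclass(frozen=True)
class FinitePopulation:
    """A fully observed universe serving as simulation ground truth.

    Attributes
    ----------
    y : (N,) study variable.
    X : (N, p) auxiliary variables; column j is variable x_j.
    Z : (N, p) instrument matrix; column j equals X[:, j] when variable
        j is exogenous, otherwise the instrument replacing it (exact
        identification keeps Z the same shape as X).
    t_y : true total of y.
    t_x : (p,) column totals of X.
    endogenous_idx : column indices flagged endogenous.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    t_y: float
    t_x: np.ndarray
    endogenous_idx: frozenset[int] = field(default_factory=frozenset)

    @property
    def N(self) -> int:
        return int(self.y.shape[0])

    @property
    def p(self) -> int:
        return int(self.X.shape[1])

    @classmethod
    def from_arrays(cls, y, X, Z=None, endogenous_idx=()) -> "FinitePopulation":
        """Build a population, computing totals by summation."""
        y = np.asarray(y, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.shape[0]:
            X = X.T
        Z = X.copy() if Z is None else np.asarray(Z, dtype=float)
        pop = cls(
            y=y,
            X=X,
            Z=Z,
            t_y=float(y.sum()),
            t_x=X.sum(axis=0),
            endogenous_idx=frozenset(int(j) for j in endogenous_idx),
        )
        pop.validate()
        return pop

    def validate(self) -> None:
        N, p = self.X.shape
        if N < 1 or p < 1:
            raise ConfigError("population needs N >= 1 units and p >= 1 auxiliaries")
        if self.y.shape != (N,) or self.Z.shape != (N, p) or self.t_x.shape != (p,):
            raise ConfigError("inconsistent population array shapes")
        if any(j < 0 or j >= p for j in self.endogenous_idx):
            raise ConfigError("endogenous column index out of range")
        if not np.isclose(self.t_y, self.y.sum(), rtol=1e-10, atol=1e-8):
            raise ConfigError("t_y does not match sum of y")
        if not np.allclose(self.t_x, self.X.sum(axis=0), rtol=1e-10, atol=1e-8):
            raise ConfigError("t_x does not match column sums of X")
        exog = [j for j in range(p) if j not in self.endogenous_idx]
        if exog and not np.array_equal(self.Z[:, exog], self.X[:, exog]):
            raise ConfigError("exogenous columns of Z must equal those of X")


@dataclass(frozen=True)
class SurveySample:
    """Drawn unit indices with inclusion probabilities and design weights.

    ``q`` holds the calibration tuning factors q_k (all 1 by default);
    they rescale the unit-level distance in chi-square calibration.
    """

    indices: np.ndarray
    N: int
    pi: np.ndarray
    d: np.ndarray
    q: np.ndarray

    @property
    def n(self) -> int:
        return int(self.indices.shape[0])

    def restrict(self, values: np.ndarray) -> np.ndarray:
        """Rows of a population-level array belonging to the sample."""
        return np.asarray(values)[self.indices]


@dataclass(frozen=True)
class TotalEstimate:
    """Point estimate of t_y with optional variance and slope."""

    estimate: float
    estimator: str
    variance: float | None = None
    beta: np.ndarray | None = None


def draw_srswor(
    population: FinitePopulation, n: int, rng: np.random.Generator
) -> SurveySample:
    """Draw a simple random sample without replacement of size n.

    Every unit gets pi_k = n/N, d_k = N/n and q_k = 1.
    """
    N = population.N
    n = int(n)
    if n < 1 or n > N:
        raise InvalidSampleSizeError(f"sample size {n} outside [1, {N}]")
    indices = np.sort(rng.choice(N, size=n, replace=False))
    f = n / N
    return SurveySample(
        indices=indices,
        N=N,
        pi=np.full(n, f),
        d=np.full(n, 1.0 / f),
        q=np.ones(n),
    )


def all_srswor_samples(N: int, n: int) -> Iterator[SurveySample]:
    """Enumerate every one of the C(N, n) equally likely SRSWOR samples.

    Intended for exhaustive design-unbiasedness checks on tiny
    populations; the count grows combinatorially.
    """
    if n < 1 or n > N:
        raise InvalidSampleSizeError(f"sample size {n} outside [1, {N}]")
    f = n / N
    for combo in combinations(range(N), n):
        yield SurveySample(
            indices=np.array(combo),
            N=N,
            pi=np.full(n, f),
            d=np.full(n, 1.0 / f),
            q=np.ones(n),
        )


def _check_aligned(sample: SurveySample, y_s: np.ndarray) -> np.ndarray:
    y_s = np.asarray(y_s, dtype=float).ravel()
    if y_s.shape[0] != sample.n:
        raise AlignmentError(
            f"sample has n={sample.n} units but y_s has length {y_s.shape[0]}"
        )
    return y_s


def ht_total(sample: SurveySample, y_s: np.ndarray) -> TotalEstimate:
    """Horvitz-Thompson estimator ``sum_s d_k y_k`` of the total."""
    y_s = _check_aligned(sample, y_s)
    return TotalEstimate(estimate=float(sample.d @ y_s), estimator="HT")


def ht_variance(sample: SurveySample, y_s: np.ndarray) -> float:
    """SRSWOR variance estimator of the HT total.

    Returns ``N^2 (1 - n/N) s^2_y / n`` with s^2_y the sample variance
    (denominator n-1).  This equals the Sen-Yates-Grundy double sum with
    the SRSWOR joint inclusion probabilities estimated through
    Delta_kl / pi_kl weighting; the closed form is used so no n-by-n
    matrix is ever materialised.
    """
    y_s = _check_aligned(sample, y_s)
    n, N = sample.n, sample.N
    if n < 2:
        raise UndefinedVarianceError("variance estimation needs n >= 2")
    s2 = float(np.var(y_s, ddof=1))
    return N**2 * (1.0 - n / N) * s2 / n
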