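"""Synthetic finite populations with endogenous auxiliaries and instruments.

The generator emulates the benchmark setting used to study calibration
under endogeneity: N units, p standard-normal auxiliary variables, a
chosen subset of which is made endogenous by loading the model error
into them through a linear first stage.  For an endogenous column j,

    z_j ~ N(0, 1)                        (the instrument)
    x_j = delta * z_j + gamma * e + nu_j,   nu_j ~ N(0, sigma_nu^2)

so x_j is correlated with both its instrument (relevance) and the error
e ~ N(0, sigma_e^2) (endogeneity), while z_j stays independent of e
(validity).  Exogenous columns are their own instruments, z_j = x_j,
which keeps Z the same shape as X (exact identification).  The study
variable is y = X beta + e and the totals t_y, t_x are computed by
summation.

Implied second moments (unit-variance z and nu scaled by sigma_nu):

    Var(x_j)      = delta^2 + gamma^2 sigma_e^2 + sigma_nu^2
    corr(x_j, e)  = gamma sigma_e / sqrt(Var(x_j))
    corr(x_j, z_j)= delta / sqrt(Var(x_j))

With the defaults delta = gamma = sigma_e = sigma_nu = 1 both
correlations equal 1/sqrt(3) ~ 0.577: moderate endogeneity and a strong
first stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._linalg import reciprocal_condition
from .design import FinitePopulation
from .exceptions import ConfigError

__all__ = ["DGPConfig", "generate_population", "diagnose_population"]


@dataclass(frozen=True)
class DGPConfig:
    """Parameters of the synthetic data-generating process.

    Defaults mirror the benchmark design: N = 1000 units, p = 20
    auxiliaries, the first column endogenous, unit slope vector, and
    unit loadings throughout.
    """

    N: int = 1000
    p: int = 20
    endogenous_idx: frozenset[int] = field(default_factory=lambda: frozenset({0}))
    beta: tuple[float, ...] | None = None  # None -> all ones
    sigma_e: float = 1.0
    gamma: float = 1.0
    delta: float = 1.0
    sigma_nu: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "endogenous_idx", frozenset(int(j) for j in self.endogenous_idx))
        if self.beta is not None:
            object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        self.validate()

    def validate(self) -> None:
        if self.N < 1:
            raise ConfigError("population size N must be >= 1")
        if self.p < 1:
            raise ConfigError("number of auxiliaries p must be >= 1")
        if self.sigma_e <= 0:
            raise ConfigError("sigma_e must be positive")
        if self.sigma_nu < 0 or self.gamma < 0:
            raise ConfigError("gamma and sigma_nu must be nonnegative")
        if any(j < 0 or j >= self.p for j in self.endogenous_idx):
            raise ConfigError("endogenous column index out of range")
        if self.beta is not None and len(self.beta) != self.p:
            raise ConfigError("beta must have length p")

    @property
    def beta_vector(self) -> np.ndarray:
        return np.ones(self.p) if self.beta is None else np.asarray(self.beta)

    def _sd_x_endog(self) -> float:
        return math.sqrt(
            self.delta**2 + (self.gamma * self.sigma_e) ** 2 + self.sigma_nu**2
        )

    def implied_corr_x_e(self) -> float:
        """Theoretical corr(x_j, e) for an endogenous column."""
        return self.gamma * self.sigma_e / self._sd_x_endog()

    def implied_corr_x_z(self) -> float:
        """Theoretical corr(x_j, z_j) for an endogenous column."""
        return self.delta / self._sd_x_endog()


def generate_population(
    config: DGPConfig, rng: np.random.Generator | None = None
) -> FinitePopulation:
    """Draw one finite population from the configured process.

    With no explicit ``rng`` a fresh generator seeded from
    ``config.seed`` is used, so the same config always yields a
    bit-identical population.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N, p = config.N, config.p
    e = rng.normal(0.0, config.sigma_e, N)
    X = np.empty((N, p))
    Z = np.empty((N, p))
    for j in range(p):
        if j in config.endogenous_idx:
            z = rng.normal(0.0, 1.0, N)
            nu = rng.normal(0.0, config.sigma_nu, N) if config.sigma_nu > 0 else 0.0
            Z[:, j] = z
            X[:, j] = config.delta * z + config.gamma * e + nu
        else:
            x = rng.normal(0.0, 1.0, N)
            X[:, j] = x
            Z[:, j] = x
    y = X @ config.beta_vector + e
    return FinitePopulation.from_arrays(y, X, Z, endogenous_idx=config.endogenous_idx)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def diagnose_population(
    pop: FinitePopulation, beta: np.ndarray | None = None
) -> dict:
    """Empirical endogeneity/instrument diagnostics of a population.

    Reports corr(x_j, z_j) per column, reciprocal condition numbers of
    X'X and Z'X, and — when the structural slope ``beta`` is supplied so
    the error can be reconstructed as e = y - X beta — corr(x_j, e) and
    corr(z_j, e) per column.
    """
    out = {
        "corr_x_z": [ _safe_corr(pop.X[:, j], pop.Z[:, j]) for j in range(pop.p) ],
        "rcond_xtx": reciprocal_condition(pop.X.T @ pop.X),
        "rcond_ztx": reciprocal_condition(pop.Z.T @ pop.X),
        "endogenous_idx": sorted(pop.endogenous_idx),
    }
    if beta is not None:
        e = pop.y - pop.X @ np.asarray(beta, dtype=float).ravel()
        out["corr_x_e"] = [_safe_corr(pop.X[:, j], e) for j in range(pop.p)]
        out["corr_z_e"] = [_safe_corr(pop.Z[:, j], e) for j in range(pop.p)]
    return out
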