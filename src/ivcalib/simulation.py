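"""Monte-Carlo harness comparing the estimators on a fixed population.

The experimental design: generate ONE finite population from a
configured process, then for each sample size n draw R independent
SRSWOR samples, evaluate every requested estimator of t_y on each, and
tabulate

    Bias = mean(t_hat) - t_y,
    MSE  = (1/R) sum_i (t_hat_i - t_y)^2,

per (estimator, n) cell.  The population is held fixed across
replications, so Bias/MSE are pure design-based (sampling) properties.

Replicate r of sample size n uses a child generator seeded
deterministically from (master seed, n, r); cells are therefore
independently reproducible and the whole summary is a pure function of
the configuration.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import greg_total
from .design import FinitePopulation, draw_srswor, ht_total
from .dgp import DGPConfig, generate_population
from .exceptions import (
    ConfigError,
    DegenerateConfigurationError,
    SingularDesignError,
)
from .ivc import ivc_total, mbivc_total

__all__ = [
    "SimulationConfig",
    "SimulationSummary",
    "run_monte_carlo",
    "summarize_to_table",
    "table_to_text",
]

#: the benchmark sample-size grid
DEFAULT_SAMPLE_SIZES = (25, 50, 75, 100, 150, 200, 250, 300, 350)
KNOWN_ESTIMATORS = ("HT", "GREG", "IVC", "MBIVC")


@dataclass(frozen=True)
class SimulationConfig:
    dgp: DGPConfig = field(default_factory=DGPConfig)
    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    R: int = 1000
    estimators: tuple[str, ...] = KNOWN_ESTIMATORS
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "sample_sizes", tuple(int(n) for n in self.sample_sizes))
        object.__setattr__(self, "estimators", tuple(self.estimators))
        if self.R < 1:
            raise ConfigError("R must be >= 1")
        for n in self.sample_sizes:
            if not 1 <= n <= self.dgp.N:
                raise ConfigError(f"sample size {n} outside [1, N={self.dgp.N}]")
        for est in self.estimators:
            if est not in KNOWN_ESTIMATORS:
                raise ConfigError(f"unknown estimator {est!r}; choose from {KNOWN_ESTIMATORS}")


@dataclass(frozen=True)
class SimulationSummary:
    """Bias/MSE grid per estimator and sample size.

    ``table`` has one row per (estimator, n) with columns
    bias, mse, empirical_variance, mean_estimate, R_effective.
    The decomposition mse = empirical_variance + bias^2 holds exactly
    (variance taken with denominator R).
    """

    table: pd.DataFrame
    t_y: float
    R: int
    seed: int


def _evaluate(est: str, pop: FinitePopulation, sample, y_s, X_s, Z_s) -> float:
    if est == "HT":
        return ht_total(sample, y_s).estimate
    if est == "GREG":
        return greg_total(sample, y_s, X_s, pop.t_x).estimate
    if est == "IVC":
        return ivc_total(sample, y_s, X_s, Z_s, pop.t_x).estimate
    if est == "MBIVC":
        return mbivc_total(y_s, X_s, Z_s, pop.t_x - X_s.sum(axis=0)).estimate
    raise ConfigError(f"unknown estimator {est!r}")


def replicate_rng(seed: int, n: int, r: int) -> np.random.Generator:
    """Deterministic child generator for replicate r at sample size n."""
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, n, r)))


def run_monte_carlo(
    config: SimulationConfig, population: FinitePopulation | None = None
) -> SimulationSummary:
    """Run the full replication grid and tabulate Bias and MSE.

    A population may be supplied directly (e.g. loaded from a file);
    otherwise one is generated from ``config.dgp`` and reused for every
    cell.  Replicates where an estimator raises a singular-design or
    weak-instrument error are dropped from that estimator's cell and
    counted in ``R_effective``; a cell losing more than 10% of its
    replicates aborts the run, flagging a degenerate configuration.
    """
    pop = generate_population(config.dgp) if population is None else population
    rows = []
    for n in config.sample_sizes:
        draws = np.full((len(config.estimators), config.R), np.nan)
        for r in range(config.R):
            rng = replicate_rng(config.seed, n, r)
            sample = draw_srswor(pop, n, rng)
            y_s = sample.restrict(pop.y)
            X_s = sample.restrict(pop.X)
            Z_s = sample.restrict(pop.Z)
            for i, est in enumerate(config.estimators):
                try:
                    draws[i, r] = _evaluate(est, pop, sample, y_s, X_s, Z_s)
                except SingularDesignError:
                    pass  # stays NaN; counted below
        for i, est in enumerate(config.estimators):
            vals = draws[i][np.isfinite(draws[i])]
            r_eff = int(vals.size)
            if r_eff < 0.9 * config.R:
                raise DegenerateConfigurationError(
                    f"estimator {est} failed on {config.R - r_eff}/{config.R} "
                    f"replicates at n={n}"
                )
            mean_est = float(vals.mean())
            bias = mean_est - pop.t_y
            mse = float(np.mean((vals - pop.t_y) ** 2))
            rows.append(
                {
                    "estimator": est,
                    "n": n,
                    "bias": bias,
                    "mse": mse,
                    "empirical_variance": float(np.var(vals)),
                    "mean_estimate": mean_est,
                    "R_effective": r_eff,
                }
            )
    table = pd.DataFrame(rows, columns=[
        "estimator", "n", "bias", "mse", "empirical_variance",
        "mean_estimate", "R_effective",
    ])
    return SimulationSummary(table=table, t_y=pop.t_y, R=config.R, seed=config.seed)


def summarize_to_table(summary: SimulationSummary) -> pd.DataFrame:
    """Rows in the benchmark table layout: Sample Size / Estimator / Bias / MSE."""
    if summary.table.empty:
        return pd.DataFrame(columns=["Sample Size", "Estimator", "Bias", "MSE"])
    out = summary.table.sort_values(["n", "estimator"], kind="stable")
    return pd.DataFrame(
        {
            "Sample Size": out["n"].to_numpy(),
            "Estimator": out["estimator"].to_numpy(),
            "Bias": out["bias"].to_numpy(),
            "MSE": out["mse"].to_numpy(),
        }
    )


def table_to_text(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of the Bias/MSE table."""
    buf = _io.StringIO()
    buf.write(table.to_string(index=False, float_format=lambda v: f"{v:12.3f}"))
    buf.write("\n")
    return buf.getvalue()
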