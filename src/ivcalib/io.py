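"""Tabular readers/writers and the estimate-from-data path.

Population tables are plain CSV with a header row and columns
``y, x1..xp, z1..zp``; z columns are optional and default to their x
counterparts.  Totals travel in a JSON sidecar with keys ``t_x`` (array)
and optional ``t_y``.  All CSV is comma-separated, UTF-8, ``.`` decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationWeights, chisq_calibration_weights, greg_total
from .design import FinitePopulation, SurveySample, draw_srswor, ht_total, ht_variance
from .exceptions import ConfigError, InvalidSampleSizeError, TableParseError
from .ivc import (
    ivc_asymptotic_variance,
    ivc_total,
    ivc_weights,
    mbivc_mse,
    mbivc_total,
    mbivc_weights,
)

__all__ = [
    "EstimationRequest",
    "read_table",
    "read_population_csv",
    "write_population_csv",
    "write_totals_json",
    "write_weights_csv",
    "run_estimate",
]


def write_population_csv(pop: FinitePopulation, path) -> None:
    p = pop.p
    data = {"y": pop.y}
    for j in range(p):
        data[f"x{j + 1}"] = pop.X[:, j]
    for j in range(p):
        data[f"z{j + 1}"] = pop.Z[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def write_totals_json(pop: FinitePopulation, path) -> None:
    payload = {"t_x": [float(v) for v in pop.t_x], "t_y": float(pop.t_y)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_totals_json(path) -> dict:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if "t_x" not in payload:
        raise TableParseError(f"totals sidecar {path} lacks required key 't_x'")
    return payload


def read_table(
    path,
    y_column: str,
    x_columns: list[str],
    z_columns: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read (y, X, Z) arrays from a CSV table.

    Missing z_columns default to the corresponding x_columns.  Rows with
    a missing value in any used column are rejected, reporting the
    offending row numbers and columns; non-numeric cells are a parse
    error.
    """
    path = Path(path)
    if not path.exists():
        raise TableParseError(f"table file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise TableParseError(f"table {path} has no data rows")
    if z_columns is not None and len(z_columns) != len(x_columns):
        raise ConfigError(
            "z_columns must pair one-to-one with x_columns (exact identification)"
        )
    used = [y_column, *x_columns, *(z_columns or [])]
    missing = [c for c in used if c not in df.columns]
    if missing:
        raise TableParseError(f"missing column(s) {missing} in {path}")
    sub = df[list(dict.fromkeys(used))]
    for col in sub.columns:
        coerced = pd.to_numeric(sub[col], errors="coerce")
        bad = coerced.isna() & sub[col].notna()
        if bad.any():
            rows = [int(i) + 2 for i in sub.index[bad][:5]]  # header is line 1
            raise TableParseError(
                f"non-numeric value(s) in column '{col}' at file line(s) {rows}"
            )
    num = sub.apply(pd.to_numeric)
    na_mask = num.isna()
    if na_mask.any().any():
        cells = [
            (int(i) + 2, c)
            for c in num.columns
            for i in num.index[na_mask[c]][:5]
        ]
        raise TableParseError(f"missing value(s) at (file line, column): {cells[:10]}")
    y = num[y_column].to_numpy(dtype=float)
    X = num[x_columns].to_numpy(dtype=float)
    Z = X.copy() if z_columns is None else num[z_columns].to_numpy(dtype=float)
    return y, X, Z


def read_population_csv(
    path, totals_path=None, endogenous_idx=()
) -> FinitePopulation:
    """Load a full population table written by :func:`write_population_csv`.

    Column roles are inferred from the ``y``/``x#``/``z#`` naming; any
    ``z#`` column absent from the file defaults to ``x#``.  If a totals
    sidecar is given, its t_x is checked against the recomputed column
    sums.
    """
    df = pd.read_csv(path)
    x_cols = sorted(
        (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if "y" not in df.columns or not x_cols:
        raise TableParseError(f"population table {path} needs columns y, x1..xp")
    z_cols = [f"z{c[1:]}" if f"z{c[1:]}" in df.columns else c for c in x_cols]
    y, X, Z = read_table(path, "y", x_cols, z_cols)
    pop = FinitePopulation.from_arrays(y, X, Z, endogenous_idx=endogenous_idx)
    if totals_path is not None:
        t_x = np.asarray(read_totals_json(totals_path)["t_x"], dtype=float)
        if not np.allclose(t_x, pop.t_x, rtol=1e-10, atol=1e-8):
            raise TableParseError(
                f"totals sidecar {totals_path} disagrees with recomputed column sums"
            )
    return pop


def write_weights_csv(
    weights: CalibrationWeights, sample: SurveySample, path
) -> None:
    pd.DataFrame(
        {
            "unit_id": sample.indices,
            "d": sample.d,
            "w": weights.w,
            "method": weights.method,
        }
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class EstimationRequest:
    """One estimate-from-data run.

    ``population_known`` mode: the table is the full universe; totals
    are computed from it and a fresh SRSWOR sample of size n is drawn.
    ``sample_with_totals`` mode: the table already is the sample; the
    population X totals must be supplied and design weights come from
    the stated population size N (SRSWOR d_k = N/n).
    """

    table: str
    mode: str  # population_known | sample_with_totals
    y_column: str
    x_columns: tuple[str, ...]
    z_columns: tuple[str, ...] | None = None
    totals: tuple[float, ...] | None = None
    n: int | None = None
    N: int | None = None
    estimators: tuple[str, ...] = ("HT", "GREG", "IVC", "MBIVC")
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("population_known", "sample_with_totals"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.z_columns is not None and len(self.z_columns) != len(self.x_columns):
            raise ConfigError("z_columns must pair one-to-one with x_columns")
        if self.mode == "sample_with_totals":
            if self.totals is None or len(self.totals) != len(self.x_columns):
                raise ConfigError(
                    "sample_with_totals mode requires a total for every x column"
                )
            if self.N is None:
                raise ConfigError("sample_with_totals mode requires the population size N")
        if self.mode == "population_known" and self.n is None:
            raise ConfigError("population_known mode requires a sample size n")


def _estimator_reports(sample, y_s, X_s, Z_s, t_x, estimators, t_y=None):
    reports = []
    for est in estimators:
        rec = {"estimator": est, "n": int(sample.n), "N": int(sample.N)}
        if est == "HT":
            res = ht_total(sample, y_s)
            rec["variance"] = ht_variance(sample, y_s) if sample.n >= 2 else None
            rec["constraint_gap"] = None
        elif est == "GREG":
            res = greg_total(sample, y_s, X_s, t_x)
            rec["variance"] = None
            rec["constraint_gap"] = chisq_calibration_weights(
                sample, X_s, t_x
            ).constraint_gap
        elif est == "IVC":
            res = ivc_total(sample, y_s, X_s, Z_s, t_x)
            rec["variance"] = (
                ivc_asymptotic_variance(sample, y_s, X_s, Z_s, t_x)
                if sample.n >= 2
                else None
            )
            rec["constraint_gap"] = ivc_weights(sample, X_s, Z_s, t_x).constraint_gap
        elif est == "MBIVC":
            t_ns = t_x - X_s.sum(axis=0)
            res = mbivc_total(y_s, X_s, Z_s, t_ns)
            rec["variance"] = mbivc_mse(y_s, X_s, Z_s, t_ns)
            rec["constraint_gap"] = mbivc_weights(X_s, Z_s, t_ns).constraint_gap
        else:
            raise ConfigError(f"unknown estimator {est!r}")
        rec["estimate"] = res.estimate
        rec["beta"] = None if res.beta is None else [float(b) for b in res.beta]
        if t_y is not None:
            rec["error_vs_true_total"] = res.estimate - t_y
        reports.append(rec)
    return reports


def run_estimate(request: EstimationRequest) -> dict:
    """Execute an estimation request and return a JSON-serializable report."""
    y, X, Z = read_table(
        request.table,
        request.y_column,
        list(request.x_columns),
        None if request.z_columns is None else list(request.z_columns),
    )
    m = y.shape[0]
    if request.mode == "population_known":
        endog = [j for j in range(X.shape[1]) if not np.array_equal(X[:, j], Z[:, j])]
        pop = FinitePopulation.from_arrays(y, X, Z, endogenous_idx=endog)
        if request.n > m:
            raise InvalidSampleSizeError(
                f"requested n={request.n} exceeds the {m} table rows"
            )
        rng = np.random.default_rng(request.seed)
        sample = draw_srswor(pop, request.n, rng)
        reports = _estimator_reports(
            sample,
            sample.restrict(pop.y),
            sample.restrict(pop.X),
            sample.restrict(pop.Z),
            pop.t_x,
            request.estimators,
            t_y=pop.t_y,
        )
        header = {"mode": request.mode, "N": pop.N, "n": int(request.n),
                  "t_y": pop.t_y, "seed": request.seed}
    else:
        N = int(request.N)
        if m > N:
            raise InvalidSampleSizeError(f"sample has {m} rows but N={N}")
        f = m / N
        sample = SurveySample(
            indices=np.arange(m),
            N=N,
            pi=np.full(m, f),
            d=np.full(m, 1.0 / f),
            q=np.ones(m),
        )
        t_x = np.asarray(request.totals, dtype=float)
        reports = _estimator_reports(sample, y, X, Z, t_x, request.estimators)
        header = {"mode": request.mode, "N": N, "n": m, "seed": request.seed}
    return {**header, "estimates": reports}
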