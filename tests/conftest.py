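import numpy as np
import pytest

from ivcalib.design import SurveySample


def make_srswor_sample(N: int, n: int, q: np.ndarray | None = None) -> SurveySample:
    """A SRSWOR-structured sample on the first n units (for algebra tests
    the identity of the drawn units is irrelevant)."""
    f = n / N
    return SurveySample(
        indices=np.arange(n),
        N=N,
        pi=np.full(n, f),
        d=np.full(n, 1.0 / f),
        q=np.ones(n) if q is None else np.asarray(q, dtype=float),
    )


def random_instance(rng: np.random.Generator, n: int, p: int, endog: int | None = 0):
    """A random calibration instance: sample, X_s, Z_s, t_x.

    Z equals X except in one column, where the instrument is the column
    plus noise (relevant but distinct); t_x is the HT auxiliary total
    perturbed so the constraints genuinely bind.
    """
    N = 5 * n
    sample = make_srswor_sample(N, n)
    X_s = rng.normal(size=(n, p))
    Z_s = X_s.copy()
    if endog is not None and p > 0:
        j = endog % p
        Z_s[:, j] = X_s[:, j] + 0.5 * rng.normal(size=n)
    t_x = X_s.T @ sample.d + rng.normal(scale=np.sqrt(n), size=p)
    return sample, X_s, Z_s, t_x


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
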