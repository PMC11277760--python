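"""Typed errors raised by the estimators and I/O layer."""


class IvcalibError(Exception):
    """Base class for all package errors."""


class InvalidSampleSizeError(IvcalibError, ValueError):
    """Requested sample size outside [1, N]."""


class AlignmentError(IvcalibError, ValueError):
    """A sample-restricted vector/matrix does not match the sample size."""


class UndefinedVarianceError(IvcalibError, ValueError):
    """Variance estimator requested with fewer than two sampled units."""


class SingularDesignError(IvcalibError, ValueError):
    """Auxiliary Gram matrix numerically rank-deficient.

    Raised when the reciprocal condition number of the solved
    cross-product matrix falls below 1e-12; the message names the
    columns implicated in the near-null space.
    """

    def __init__(self, message: str, columns=None, rcond: float | None = None):
        super().__init__(message)
        self.columns = tuple(columns) if columns is not None else ()
        self.rcond = rcond


class WeakInstrumentError(SingularDesignError):
    """Instrument/auxiliary cross-Gram Z'X numerically singular.

    Signals instruments that are (numerically) irrelevant for the
    auxiliary variables they replace; carries the reciprocal condition
    number of Z'X so callers can report instrument strength.
    """


class NotSupportedError(IvcalibError, ValueError):
    """Requested configuration outside scope (e.g. over-identification)."""


class ConfigError(IvcalibError, ValueError):
    """Invalid generator or simulation configuration."""


class TableParseError(IvcalibError, ValueError):
    """Malformed input table: missing column, non-numeric or missing cell."""


class DegenerateConfigurationError(IvcalibError, RuntimeError):
    """More than 10% of Monte-Carlo replicates failed in one cell."""
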