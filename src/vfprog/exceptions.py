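"""Exception hierarchy shared across the package."""


class VFProgError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(VFProgError, ValueError):
    """A distribution or model parameter is outside its domain."""


class DataError(VFProgError, ValueError):
    """Input data violate a structural contract (schema, finiteness, size)."""


class ScheduleError(DataError):
    """A test schedule is degenerate (all times equal, too few tests)."""


class ConfigError(VFProgError, ValueError):
    """A generator / run configuration is invalid."""


class ConvergenceError(VFProgError, RuntimeError):
    """MCMC did not reach the convergence threshold.

    Carries the offending split-R-hat values in ``rhat``.
    """

    def __init__(self, message: str, rhat: dict | None = None):
        super().__init__(message)
        self.rhat = rhat or {}
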