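"""Exception types shared across the package."""


class GelfrontError(Exception):
    """Base class for all package errors."""


class ContractError(GelfrontError, ValueError):
    """A precondition or invariant was violated; message names the offending field."""


class SolverError(GelfrontError, RuntimeError):
    """Time integration failed.

    Attributes
    ----------
    last_time : float or None
        Last time accepted by the integrator before failure, seconds.
    """

    def __init__(self, message, last_time=None):
        super().__init__(message)
        self.last_time = last_time


class ConfigError(GelfrontError, ValueError):
    """Configuration file invalid; message aggregates every violation found."""
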