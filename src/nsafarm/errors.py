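"""Exception hierarchy shared across the package."""


class NSAFarmError(Exception):
    """Base class for all package errors."""


class ParameterError(NSAFarmError, ValueError):
    """A parameter violates its documented domain (sign, range, units)."""


class DivergentFeedbackError(NSAFarmError, ValueError):
    """The forage–manure feedback loop is supercritical and has no finite
    steady state (beta * rho_f * (1 - gamma) * alpha >= 1)."""


class ConvergenceError(NSAFarmError, RuntimeError):
    """An iterative solver failed to converge within its iteration cap."""


class TableError(NSAFarmError, ValueError):
    """An input table fails validation (missing rows, bad shares, units)."""


class ConfigError(NSAFarmError, ValueError):
    """A run configuration is malformed or references missing inputs."""


class EnsembleError(NSAFarmError, RuntimeError):
    """Too many Monte Carlo realizations failed to solve."""
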