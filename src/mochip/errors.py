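"""Exception hierarchy for the mochip package."""


class MochipError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MochipError, ValueError):
    """A physical parameter or argument violates its domain constraint."""


class ConfigError(MochipError, ValueError):
    """A configuration file is missing keys, has unknown keys, or holds
    non-physical values. The message names the offending key."""


class StabilityError(MochipError, RuntimeError):
    """A requested time step exceeds the explicit-scheme stability bound."""


class NumericalFailureError(MochipError, RuntimeError):
    """The solver produced NaN/Inf concentrations."""


class DegenerateDataError(MochipError, ValueError):
    """Observations cannot constrain the requested fit (e.g. all samples at
    one rocking phase, or a negative variance-growth slope)."""
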