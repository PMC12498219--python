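"""Exception hierarchy shared across the toolkit."""


class VhitError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(VhitError, ValueError):
    """A simulation or algorithm parameter is out of its valid domain."""


class InputError(VhitError, ValueError):
    """An input trace, trial, or table violates a precondition."""


class FormatError(VhitError, ValueError):
    """A file being read does not conform to the documented format."""


class UndefinedGainError(VhitError, ArithmeticError):
    """Gain is undefined for this input (e.g. zero head velocity)."""


class UndefinedStatisticError(VhitError, ArithmeticError):
    """A statistic is undefined for this input (e.g. constant vector)."""


class ConfigError(VhitError, ValueError):
    """Pipeline configuration is invalid or incomplete."""


class SeparationWarning(UserWarning):
    """Logistic fit shows signs of (quasi-)separation; consider firth."""
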