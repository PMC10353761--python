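"""Exception hierarchy.

``InputError`` covers malformed data passed to an operation,
``ConfigError`` covers invalid configuration values (it names the
offending field), and ``SeparationError`` signals perfect separation in a
logistic fit, where maximum-likelihood coefficients diverge.
"""


class ComaSpectraError(Exception):
    """Base class for all package errors."""


class InputError(ComaSpectraError):
    """Invalid input data (wrong shape, empty group, bad channel set ...)."""


class ConfigError(ComaSpectraError):
    """Invalid configuration value; message names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class SeparationError(ComaSpectraError):
    """Perfect separation in a binomial GLM; coefficients are unbounded."""
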