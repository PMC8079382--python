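"""Exception hierarchy."""


class TagnetError(Exception):
    """Base class for all tagnet errors."""


class ConfigError(TagnetError):
    """Invalid configuration value; message names the offending field."""


class DataError(TagnetError):
    """Malformed or inconsistent input data."""


class ConvergenceError(TagnetError):
    """Iterative solver failed to converge within its iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
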