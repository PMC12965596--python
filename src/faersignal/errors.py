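"""Exception hierarchy shared across the package."""


class FaersignalError(Exception):
    """Base class for all package errors."""


class ConfigError(FaersignalError):
    """Invalid configuration value; ``field`` names the offending key."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class SchemaError(FaersignalError):
    """Input table does not match the expected schema."""

    def __init__(self, column: str, path: str):
        self.column = column
        self.path = path
        super().__init__(f"required column '{column}' missing from {path}")


class DataError(FaersignalError):
    """Input data violates a precondition (empty cohort, empty database, ...)."""


class FitError(FaersignalError):
    """An iterative fit failed to converge.

    Carries the last iterate and the objective trace for post-mortem.
    """

    def __init__(self, message: str, last_iterate=None, trace=None):
        self.last_iterate = last_iterate
        self.trace = list(trace) if trace is not None else []
        super().__init__(message)
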