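"""Exception hierarchy shared across the package."""


class RSAError(Exception):
    """Base class for all rsataper errors."""


class InputError(RSAError, ValueError):
    """Malformed or inconsistent user input (counts, shapes, values)."""


class InsufficientDataError(InputError):
    """Not enough observations to perform the requested fit."""


class DegenerateGeometryError(RSAError):
    """Geometric configuration that makes the operation undefined."""


class IllConditionedError(RSAError):
    """Linear system too close to singular to solve reliably."""


class ConvergenceError(RSAError):
    """Iterative optimizer failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConsistencyError(RSAError):
    """Inputs that should agree with each other do not."""


class UndefinedStatisticError(RSAError):
    """Statistic is undefined for the given data (e.g. zero variance)."""
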