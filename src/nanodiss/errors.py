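"""Exception types shared across the package."""


class NanodissError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NanodissError, ValueError):
    """Invalid input data (bad units, nonpositive quantity, malformed table)."""


class DomainError(NanodissError, ValueError):
    """Argument outside the mathematical domain of a closed-form relation."""


class GeometryError(NanodissError, ValueError):
    """Degenerate crystallographic geometry (nonpositive cell discriminant)."""


class RegressionError(NanodissError, ValueError):
    """Degenerate point set for a least-squares fit."""


class ConvergenceError(NanodissError, RuntimeError):
    """Dissolution integration did not reach equilibrium within the step budget."""

    def __init__(self, message: str, *, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
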