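"""Exception types raised across the package."""


class StenoflowError(Exception):
    """Base class for package errors."""


class ValidationError(StenoflowError, ValueError):
    """Invalid argument values (negative lengths, out-of-range fractions, ...)."""


class GeometryError(ValidationError):
    """Degenerate or unphysical geometry (e.g. severity >= 1)."""


class MeshingError(StenoflowError):
    """Mesh generation produced an invalid grid (inverted cells, ...)."""


class NumericalFailureError(StenoflowError):
    """NaN/Inf appeared in a solver field."""


class NonConvergenceError(StenoflowError):
    """Residuals diverged; carries the convergence report."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report
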