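"""Exception hierarchy.

All package-specific errors derive from :class:`ReesError` so callers (and
the CLI) can distinguish validation problems from numerical failures.
"""


class ReesError(Exception):
    """Base class for all reesfit errors."""


class SpectralFormatError(ReesError, ValueError):
    """A spectral or melt table could not be parsed as specified."""


class GridMismatchError(ReesError, ValueError):
    """Two datasets do not share the wavelength grids an operation requires."""


class DegenerateSpectrumError(ReesError, ValueError):
    """A spectrum has no positive total intensity, so CSM is undefined."""


class ValidationError(ReesError, ValueError):
    """Inputs violate a precondition (too few points, bad window, ...)."""


class ConvergenceError(ReesError, RuntimeError):
    """A nonlinear fit failed to converge.

    Carries the initial parameter values that were tried, to aid diagnosis.
    """

    def __init__(self, message: str, initial_values: dict | None = None):
        super().__init__(message)
        self.initial_values = dict(initial_values or {})


class NonIdentifiableError(ReesError, RuntimeError):
    """The data carry no information about a requested parameter."""


class ModelEvaluationError(ReesError, FloatingPointError):
    """A closed-form model evaluation overflowed for the given parameters."""
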