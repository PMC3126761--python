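"""Exception hierarchy for poremetry."""


class PoremetryError(Exception):
    """Base class for all poremetry errors."""


class InvalidParameterError(PoremetryError, ValueError):
    """A parameter violates a documented precondition."""


class DegeneratePhantomError(PoremetryError):
    """A synthetic phantom has no pixels left in one of the two phases."""


class DegenerateImageError(PoremetryError):
    """An image cannot be thresholded (e.g. a single intensity value)."""


class DegenerateMaskError(PoremetryError):
    """A binary mask contains only one phase where two are required."""


class InsufficientDataError(PoremetryError):
    """Too few data points for a fit (e.g. < 3 isotherm points in the BET window)."""


class InvalidFitError(PoremetryError):
    """A model fit produced physically meaningless parameters (e.g. BET C <= 0)."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EmptyProfileError(PoremetryError):
    """No radius samples fall within the interface-depth ceiling."""
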