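"""Exception hierarchy for bbbflux."""


class BBBFluxError(Exception):
    """Base class for all bbbflux errors."""


class ConfigError(BBBFluxError):
    """Invalid configuration or parameter value."""


class MetadataError(BBBFluxError):
    """A required acquisition-metadata field is missing or invalid."""


class ShapeError(BBBFluxError):
    """Declared hyperstack shape is inconsistent with the stored data."""


class PlacementError(BBBFluxError):
    """Vessels or ROIs could not be placed under the stated constraints."""

    def __init__(self, message: str, achieved: int | None = None):
        super().__init__(message)
        self.achieved = achieved


class SegmentationError(BBBFluxError):
    """Vessel segmentation produced no usable foreground."""


class FitError(BBBFluxError):
    """Nonlinear fit did not converge, even after the linear fallback."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class TraceError(BBBFluxError):
    """An intensity trace violates a precondition (empty ROI, bad baseline...)."""
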