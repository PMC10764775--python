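"""Exception hierarchy for the bitekin pipeline."""


class BitekinError(Exception):
    """Base class for all bitekin errors."""


class LandmarkDataError(BitekinError):
    """Raised for structurally invalid landmark tables (missing roles,
    non-uniform time steps, interior gaps, non-finite coordinates)."""


class CalibrationError(BitekinError):
    """Raised for invalid or repeated pixel-to-mm calibration."""


class GeometryError(BitekinError):
    """Raised when a geometric computation is degenerate (zero-length
    angle arm, coincident benthos points, out-of-range rotation)."""


class DetectionError(BitekinError):
    """Raised when an event detector cannot find what it needs
    (no closure onset, no gape cycle)."""


class SeparationError(BitekinError):
    """Raised when a logistic fit diverges due to complete or
    quasi-complete separation of the response."""


class StatsError(BitekinError):
    """Raised for statistically degenerate inputs (zero-variance
    predictor, single-class response, too few observations)."""
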