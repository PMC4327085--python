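"""Exception hierarchy for the sidegait pipeline."""


class SidegaitError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SidegaitError):
    """Malformed or inconsistent depth-frame input."""


class InvalidDepthError(SidegaitError, ValueError):
    """A metric conversion was requested at a non-positive depth."""


class NoSubjectError(SidegaitError):
    """No foreground component found in the frame."""


class CalibrationError(SidegaitError):
    """Front-plane pose analysis failed (bad pose or degenerate silhouette)."""


class PoseError(CalibrationError):
    """Subject's pose violates a calibration precondition (e.g. arms not out)."""


class TrackingError(SidegaitError):
    """A per-frame joint locator failed; the joint is missing for that frame."""


class ValidationError(SidegaitError):
    """Trajectory comparison could not be carried out."""


class RenderError(SidegaitError):
    """Synthetic figure does not fit the camera frustum."""
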