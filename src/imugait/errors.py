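"""Exception hierarchy for the gait-analysis pipeline.

Every stage raises a subclass of :class:`ImuGaitError`, so callers (and the
CLI) can attach the stage name and offending input file when propagating.
"""


class ImuGaitError(Exception):
    """Base class for all package errors."""


class FormatError(ImuGaitError):
    """A file does not match the expected CSV dialect (e.g. wrong column count)."""


class DataError(ImuGaitError):
    """File parsed but the contents violate an invariant (e.g. non-monotone time)."""


class AlignmentError(ImuGaitError):
    """Two sensor streams cannot be placed on a common time base."""


class IntegrationError(ImuGaitError):
    """Trajectory integration preconditions violated (non-uniform grid)."""


class CalibrationError(ImuGaitError):
    """Drift calibration cannot be anchored (missing stance windows, zero X_end)."""


class EventError(ImuGaitError):
    """Gait-cycle segmentation or parameter extraction failed."""


class ScoreError(ImuGaitError):
    """Gait-score computation is degenerate (too few steps, zero pitch range)."""


class CorrelationError(ImuGaitError):
    """Correlation undefined (zero variance / all-tied input)."""


class ConfigError(ImuGaitError):
    """Invalid model or pipeline configuration."""


class ShapeError(ImuGaitError):
    """Array arguments have incompatible shapes."""


class TrainingError(ImuGaitError):
    """Model training cannot proceed (e.g. empty dataset)."""
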