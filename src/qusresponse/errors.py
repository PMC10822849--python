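"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`QUSError` so drivers can separate
scientific failures (a block that cannot be fitted) from programming errors.
"""


class QUSError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(QUSError, ValueError):
    """Malformed input: bad shapes, impossible parameter values, empty data."""


class AlignmentError(QUSError):
    """Two spectra or frames that must share a grid/geometry do not."""


class InsufficientSupportError(QUSError):
    """Not enough in-band points / ROI area to carry out an estimate."""


class FitFailureError(QUSError):
    """A model fit has no solution in the admissible region (e.g. a
    non-decaying backscatter spectrum has no real effective radius)."""


class DegenerateFitError(QUSError):
    """Classifier training data carry no usable signal (constant features,
    single class)."""
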