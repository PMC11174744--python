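"""Exception hierarchy for the gaitpix pipeline.

Every stage raises a subclass of :class:`GaitPixError`, so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class GaitPixError(Exception):
    """Base class for all gaitpix errors."""


class SchemaError(GaitPixError):
    """A CSV file does not match the documented column schema."""


class ValidationError(GaitPixError):
    """Input data violates a documented invariant (e.g. non-monotonic time)."""


class ParameterError(GaitPixError):
    """An operation was called with an invalid parameter value."""


class UndefinedAngleError(GaitPixError):
    """Angle requested at a vertex with coincident points."""


class EmptySeriesError(GaitPixError):
    """A joint-angle series could not be computed for any frame."""


class ExtrapolationError(GaitPixError):
    """Resampling was requested outside the time span of the series."""


class CalibrationError(GaitPixError):
    """Fiducial-marker observations are degenerate or missing."""


class MeasurementError(GaitPixError):
    """An anthropometric measurement could not be taken."""


class NonStaticCaptureError(MeasurementError):
    """The subject moved too much for a static anthropometric capture."""


class EstimationError(GaitPixError):
    """Not enough data to estimate a quantity (e.g. the ground line)."""


class AlignmentError(GaitPixError):
    """Two time series have no temporal overlap to compare on."""


class ConfigurationError(GaitPixError):
    """A simulation or run configuration is invalid or infeasible."""
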