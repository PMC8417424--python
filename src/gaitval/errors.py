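"""Exception hierarchy.

Errors are grouped into three families that the command-line layer maps to
exit codes: input-format problems, validation problems (events, markers,
geometry), and statistical degeneracies.
"""


class GaitvalError(Exception):
    """Base class for all package errors."""


# --- input / format -------------------------------------------------------

class FormatError(GaitvalError):
    """A file does not follow the expected dialect (headers, columns)."""


class ParseError(FormatError):
    """A cell could not be parsed; message carries frame/marker context."""


class ConfigError(GaitvalError):
    """A required trial-configuration field is missing or inconsistent."""


# --- validation -----------------------------------------------------------

class ValidationError(GaitvalError):
    """Base for semantic validation failures."""


class EventOrderError(ValidationError):
    """Contact/liftoff events do not alternate or are not increasing."""


class InsufficientEventsError(ValidationError):
    """Fewer than two contacts: no cycle can be built."""


class NoGaitDetectedError(ValidationError):
    """The toe trajectory shows no periodic rostro-caudal motion."""


class MissingMarkerError(ValidationError):
    """A marker required by the requested computation is absent."""


class UnusableMarkerError(ValidationError):
    """A marker has no confident frames at all; it cannot be gap-filled."""


class DegenerateGeometryError(ValidationError):
    """Coincident points make an angle or segment undefined."""


class UnreachablePoseError(ValidationError):
    """Segment lengths violate the triangle inequality for the pose."""


class TooShortCycleError(ValidationError):
    """A cycle with fewer than two frames cannot be resampled."""


class InvalidTemplateError(ValidationError):
    """A synthetic joint template produced an impossible limb chain."""


class AlignmentError(ValidationError):
    """Two variable tables do not share the same cycle index."""


# --- statistical degeneracy ----------------------------------------------

class StatisticalError(GaitvalError):
    """Base for undefined statistics."""


class DegenerateDistributionError(StatisticalError):
    """Zero-variance sample: normal quantile comparison is undefined."""


class UndefinedStatisticError(StatisticalError):
    """ICC/CCC/CC undefined (e.g. zero subject variance)."""
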