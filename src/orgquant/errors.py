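"""Exception hierarchy.

``ParameterError`` marks caller mistakes (bad flags/arguments, CLI exit code 2);
``DataError`` and its subclasses mark problems with the data itself
(CLI exit code 3).
"""


class OrgQuantError(Exception):
    """Base class for all package errors."""


class ParameterError(OrgQuantError, ValueError):
    """A parameter is outside its documented range or inconsistent."""


class DataError(OrgQuantError):
    """Input data violates an operation's precondition."""


class FrameMismatchError(DataError):
    """Image and geometry are not in the same coordinate frame."""


class CenterOutsideError(DataError):
    """A supplied or computed cell center is not strictly inside the contour."""


class DegenerateContourError(DataError):
    """Contour approximation collapsed below 3 vertices."""


class ClusterTooSmallError(DataError):
    """Cluster too small to carry a boundary."""


class PathBoundsError(DataError):
    """A kymograph path leaves the image bounds."""


class InsufficientDataError(DataError):
    """Not enough observations to run the requested computation."""


class TrackTooShortError(DataError):
    """A track has fewer than 2 points."""


class InvalidProfileError(DataError):
    """A radial profile with zero total intensity has no defined score."""


class FormatError(DataError):
    """Unsupported or malformed file content."""


class ChannelRequiredError(FormatError):
    """A multi-channel image was given without selecting a channel."""


class OutputCollisionError(DataError):
    """Output files already exist and --overwrite was not given."""


class SimulationSpecError(DataError):
    """A synthetic-data spec is internally infeasible."""
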