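"""Exception hierarchy shared across the package."""


class ForestSpatError(Exception):
    """Base class for all forestspat errors."""


class FormatError(ForestSpatError):
    """A delimited-text input does not have the required structure."""


class ValidationError(ForestSpatError):
    """A stem record or stem map violates a data-model invariant."""


class GeometryError(ForestSpatError):
    """A quadrat grain or window request is geometrically impossible."""


class InsufficientPointsError(ForestSpatError):
    """A point-pattern statistic was asked for with too few points."""


class GridMismatchError(ForestSpatError):
    """Summary curves evaluated on different r-grids were combined."""


class SimulatorError(ForestSpatError):
    """A point-process simulator could not produce a valid realization."""


class PackingFailureError(SimulatorError):
    """Simple sequential inhibition ran out of attempts.

    Attributes
    ----------
    points_placed : int
        Number of points successfully placed before the failure.
    """

    def __init__(self, message: str, points_placed: int = 0):
        super().__init__(message)
        self.points_placed = points_placed
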