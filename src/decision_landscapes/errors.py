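"""Exception hierarchy shared across the package."""


class DecisionLandscapeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DecisionLandscapeError):
    """Input file does not conform to the expected tabular schema."""


class EmptyInputError(DecisionLandscapeError):
    """An operation received no data to work on."""


class GeometryError(DecisionLandscapeError):
    """Screen geometry is degenerate (zero horizontal or vertical span)."""


class DegenerateTrajectoryError(DecisionLandscapeError):
    """Trajectory carries no usable motion (static, tied, or single-sample)."""


class ParameterError(DecisionLandscapeError):
    """An argument violates its contract (bad alpha, n_points, ranges...)."""


class AlignmentError(DecisionLandscapeError):
    """Trajectory and velocity profile (or parallel lists) have mismatched lengths."""


class PreconditionError(DecisionLandscapeError):
    """Operation called on data that has not been through the required step."""


class SimulationError(DecisionLandscapeError):
    """Forward integration stalled or blew up."""
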