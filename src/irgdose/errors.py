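"""Exception hierarchy.

Every error raised by the package derives from :class:`IrgdoseError`, so
callers (and the CLI) can catch one type and exit cleanly.
"""


class IrgdoseError(Exception):
    """Base class for all package errors."""


class ConfigError(IrgdoseError):
    """Invalid programme definition, simulation config or run options."""


class IncompleteAssignmentError(ConfigError):
    """The strategy assignment does not cover every (setting, intervention) pair."""


class ScoreRangeError(IrgdoseError):
    """A score lies outside the [0, mas] scale."""


class InsufficientRatersError(IrgdoseError):
    """Fewer than two expert scores were supplied for a cell."""


class InconsistentCellError(IrgdoseError):
    """Scores from different cells or rounds were mixed in one summary."""


class ProtocolViolationError(IrgdoseError):
    """Round-2 scores supplied for a cell the consensus rule never flagged."""


class IncompleteCalibrationError(IrgdoseError):
    """A group is missing fictitious-IRG scores, so offsets cannot be computed."""


class MissingOffsetError(IrgdoseError):
    """A scored cell's group has no calibration offset."""


class ConsistencyError(IrgdoseError):
    """Data contradicts the programme structure (e.g. a PDA score for a control IRG)."""


class RosterError(IrgdoseError):
    """A target's setting is unknown to the programme."""


class InsufficientGroupError(IrgdoseError):
    """An arm of a contrast is empty."""


class DegenerateDesignError(IrgdoseError):
    """A factorial cell of an interaction design is empty."""
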