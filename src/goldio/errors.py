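"""Exception hierarchy for the goldio pipeline.

Workflow code raises these instead of bare ValueError so the CLI can log a
failed workflow and keep running the remaining ones.
"""


class GoldioError(Exception):
    """Base class for all goldio-specific failures."""


class InvalidMaskError(GoldioError):
    """ROI mask has no analyzable pixels (or is otherwise unusable)."""


class FormatError(GoldioError):
    """An on-disk input does not match the expected format."""


class AmbiguousInputError(FormatError):
    """A folder-discovery keyword matched more than one file."""

    def __init__(self, keyword: str, candidates):
        self.keyword = keyword
        self.candidates = sorted(str(c) for c in candidates)
        super().__init__(
            f"keyword {keyword!r} matches multiple files: {', '.join(self.candidates)}"
        )


class MissingInputError(FormatError):
    """A mandatory input file (mask or gold CSV) was not found."""


class InsufficientPointsError(GoldioError):
    """An operation needs more points than the set provides."""


class MissingLandmarkError(GoldioError):
    """A landmark-based workflow was invoked without landmarks."""


class InsufficientClustersError(GoldioError):
    """Fewer qualifying clusters than the separation analysis requires."""


class SaturationError(GoldioError):
    """Random-point generation could not place the requested number of points."""

    def __init__(self, placed: int, requested: int, max_attempts: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed}/{requested} points before exhausting "
            f"{max_attempts} attempts; mask too small or min_separation too "
            f"large for the requested count"
        )


class ConfigError(GoldioError):
    """A run/simulation configuration is internally inconsistent."""
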