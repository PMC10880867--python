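"""Exception hierarchy for the sit-to-stand analysis pipeline.

Every pipeline-specific failure derives from :class:`SitStandError` so callers
can catch one base class at the application boundary while tests assert the
precise subtype.
"""


class SitStandError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SitStandError):
    """A file or record does not conform to the expected dialect."""


class ParseError(FormatError):
    """Malformed content that could not be parsed at all."""


class SchemeError(SitStandError):
    """A joint name or joint count does not resolve in the keypoint scheme."""


class GapError(SitStandError):
    """An unrecoverable run of missing/low-confidence frames."""

    def __init__(self, joint: int, start: int, stop: int, message: str = ""):
        self.joint = joint
        self.start = start
        self.stop = stop
        super().__init__(
            message
            or f"unrecoverable gap at joint {joint}, frames {start}..{stop - 1}"
        )


class DegenerateGeometryError(SitStandError):
    """A zero-length limb vector makes the joint angle undefined."""


class ShortSeriesError(SitStandError):
    """A series is shorter than the normalization target."""

    def __init__(self, n: int, target: int):
        self.n = n
        self.target = target
        super().__init__(f"series of length {n} is shorter than target {target}")


class AggregationError(SitStandError):
    """Curves cannot be aggregated (empty pool or mixed lengths)."""


class ClassificationError(SitStandError):
    """A WOMAC score falls outside every defined severity interval."""


class IncompleteRecordError(SitStandError):
    """A subject lacks a series required for one of its affected sides."""


class CohortError(SitStandError):
    """A cohort request cannot be satisfied (e.g. too few subjects per group)."""


class ComparisonError(SitStandError):
    """Two wavelet decompositions are not comparable."""


class ConfigurationError(SitStandError):
    """Invalid analysis or simulation configuration."""
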