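"""Exception hierarchy.

Every error raised by this package derives from :class:`SenescanError`, so
callers can catch one type at a pipeline boundary.
"""


class SenescanError(Exception):
    """Base class for all senescan errors."""


class SchemaError(SenescanError):
    """A required column or channel role is missing or unresolvable."""


class ParseError(SenescanError):
    """A cell in a delimited input could not be parsed as a number."""


class FormatError(SenescanError):
    """A binary container (FCS) is malformed or unsupported."""


class MergeError(SenescanError):
    """Tables with incompatible feature column sets were merged."""


class SegmentationEmptyError(SenescanError):
    """Segmentation produced no foreground pixels."""


class AlignmentError(SenescanError):
    """Mask/image shapes or score-vector lengths do not match."""


class EstimationError(SenescanError):
    """Not enough (or degenerate) data to estimate a threshold/coefficient."""


class UndefinedLossError(SenescanError):
    """Large-cell loss is undefined (no large events in the reference gate)."""


class ReferenceStatsError(SenescanError):
    """Reference statistics could not be computed (too few events, bad data)."""


class NormalizationError(SenescanError):
    """Normalization against a zero or negative reference mean."""


class RankingError(SenescanError):
    """Feature ranking requires two non-empty truth groups."""


class TruthError(SenescanError):
    """One of the truth populations is empty."""


class TrainingError(SenescanError):
    """Classifier training preconditions are violated."""


class NoSignalError(TrainingError):
    """No candidate feature discriminates the truth populations."""


class CapabilityError(SenescanError):
    """The requested operation needs inputs (images/flags) that are absent."""


class ConfigError(SenescanError):
    """Invalid or incomplete configuration."""


class RenderError(SenescanError):
    """A synthetic cell does not fit in the requested image crop."""


class SummaryError(SenescanError):
    """Per-sample summary undefined (no gated singles)."""
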