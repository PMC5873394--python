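"""Exception hierarchy for hgtclock.

All errors raised by the library derive from :class:`HgtClockError` so callers
can catch one base class at the CLI boundary.
"""


class HgtClockError(Exception):
    """Base class for all hgtclock errors."""


class TraceParseError(HgtClockError):
    """A line of a datedist stream could not be parsed as newick."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyTraceError(HgtClockError):
    """The stream contained no tree lines."""


class LeafSetMismatchError(HgtClockError):
    """Samples in one trace do not share an identical leaf-label set."""


class UltrametricityError(HgtClockError):
    """Root-to-leaf path sums disagree beyond tolerance."""


class NotMonophyleticError(HgtClockError):
    """A clade's leaf set is not monophyletic in a sample (strict mode)."""


class NoStemNodeError(HgtClockError):
    """Stem requested for a clade whose MRCA is the root."""


class UnknownTaxonError(HgtClockError):
    """A referenced leaf label is absent from the tree."""


class AnnotationMismatchError(HgtClockError):
    """Summary rows do not cover the topology's internal nodes."""


class FormatError(HgtClockError):
    """A structured input file violates its dialect."""


class InvalidConstraintError(HgtClockError):
    """An HGT constraint is internally inconsistent (e.g. donor == recipient)."""


class InsufficientSamplesError(HgtClockError):
    """Too few samples for the requested summary statistic."""


class PairingError(HgtClockError):
    """Paired-mode probability requested on traces of unequal length."""


class InfeasibleSpecError(HgtClockError):
    """Calibration bounds admit no age assignment on the given topology."""


class ComparisonError(HgtClockError):
    """Two run reports share no clade names."""
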