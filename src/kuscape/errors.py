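"""Exception hierarchy for the kuscape pipeline.

Every anticipated failure mode gets its own class so callers (and the CLI)
can map errors onto actionable messages without string matching.
"""


class KuscapeError(Exception):
    """Base class for all pipeline errors."""


# --- io_formats ---------------------------------------------------------


class RaggedAlignmentError(KuscapeError):
    """Alignment rows differ in length."""


class EmptyFileError(KuscapeError):
    """Input file contains no usable records."""


class IllegalCharacterError(KuscapeError):
    """Sequence contains a symbol outside the accepted protein alphabet."""


class MissingColumnError(KuscapeError):
    """Required column absent from a tabular input."""


class DuplicateSpeciesError(KuscapeError):
    """Species identifier appears more than once in a profile table."""


class NonPositiveSizeError(KuscapeError):
    """Genome size is zero or negative."""


class NewickParseError(KuscapeError):
    """Newick string could not be parsed as a single rooted tree."""


class DuplicateTipError(KuscapeError):
    """Tree contains duplicated tip labels."""


# --- phyletic -----------------------------------------------------------


class EmptyProfileError(KuscapeError):
    """Phyletic profile has no rows."""


class DegenerateGroupError(KuscapeError):
    """One of the contrasted groups is empty."""


class UnknownTipError(KuscapeError):
    """A tip state refers to a label not present on the tree."""


# --- insertions ---------------------------------------------------------


class PartitionMismatchError(KuscapeError):
    """Focal/background partition inconsistent with the alignment's taxa."""


class ForeignBlocksError(KuscapeError):
    """Blocks belong to a different orthogroup than the alignment."""


class UnknownTaxonError(KuscapeError):
    """Taxon id not present in the alignment."""


class OutOfRangeError(KuscapeError):
    """Column interval outside the alignment."""


class IntervalOutOfRangeError(KuscapeError):
    """Residue interval outside the protein sequence."""


# --- stats --------------------------------------------------------------


class EmptyPoolError(KuscapeError):
    """No insertion residues available for composition analysis."""


class InsufficientOverlapError(KuscapeError):
    """Too few shared defined-enrichment amino acids between tables."""


class TooFewPairsError(KuscapeError):
    """Fewer than the minimum number of paired orthogroups."""


class NoFlankColumnsError(KuscapeError):
    """No gap-free columns fall inside the flank windows."""


class NoDistalColumnsError(KuscapeError):
    """No gap-free columns fall outside the flank windows."""


class TooFewAlignmentsError(KuscapeError):
    """Fewer alignments than required for a correlation."""


class ConstantInputError(KuscapeError):
    """A correlation input vector is constant."""


# --- synthetic ----------------------------------------------------------


class InvalidParamsError(KuscapeError):
    """Simulation parameters violate their documented ranges."""


# --- cli ----------------------------------------------------------------


class ConfigError(KuscapeError):
    """Pipeline configuration is invalid (missing path, bad parameter)."""


class StageError(KuscapeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
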