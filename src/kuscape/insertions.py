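"""Detection of lineage-specific insertions in protein alignments.

An insertion-candidate column is one where at least one focal taxon has a
residue while (essentially) all background taxa have a gap — the alignment
signature of sequence inserted on the focal lineage. Maximal runs of such
columns, optionally merged across short non-candidate stretches, become
:class:`~kuscape.io_formats.InsertionBlock` records carrying both column
and ungapped-residue coordinates, so blocks can be quantified per
alignment and mapped onto protein structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ForeignBlocksError,
    IntervalOutOfRangeError,
    OutOfRangeError,
    PartitionMismatchError,
    UnknownTaxonError,
)
from .io_formats import GAP, Alignment, InsertionBlock, PeptideSet

__all__ = [
    "FocalPartition",
    "FractionRecord",
    "DetectionParams",
    "classify_columns",
    "detect_insertion_blocks",
    "insertion_fraction",
    "map_columns_to_residues",
    "peptide_coverage",
]


@dataclass(frozen=True)
class FocalPartition:
    """Disjoint split of alignment taxa into focal and background sets."""

    focal: frozenset[str]
    background: frozenset[str]

    def __init__(self, focal: Iterable[str], background: Iterable[str]):
        object.__setattr__(self, "focal", frozenset(focal))
        object.__setattr__(self, "background", frozenset(background))
        if not self.focal or not self.background:
            raise PartitionMismatchError("focal and background must both be non-empty")
        overlap = self.focal & self.background
        if overlap:
            raise PartitionMismatchError(
                f"taxa in both focal and background: {sorted(overlap)}"
            )

    def validate(self, aln: Alignment) -> None:
        extra = (self.focal | self.background) - set(aln.taxa)
        if extra:
            raise PartitionMismatchError(
                f"{aln.id}: partition names taxa not in alignment: {sorted(extra)}"
            )


@dataclass(frozen=True)
class FractionRecord:
    """Share of an alignment's columns occupied by one taxon's insertions."""

    orthogroup: str
    taxon: str
    inserted_cols: int
    total_cols: int

    @property
    def fraction(self) -> float:
        return self.inserted_cols / self.total_cols


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds of the insertion caller.

    ``bg_gap_frac`` — minimum fraction of background taxa gapped for a
    column to be a candidate (1.0 = strict, every background taxon must be
    gapped). ``merge_gap`` — maximum run of non-candidate columns merged
    over when joining adjacent candidate runs. ``min_len`` — minimum focal
    residues inside a run for a block to be emitted (suppresses
    single-residue alignment noise). ``ignore_terminal_gaps`` — treat
    leading/trailing gap runs of background taxa as missing data rather
    than gaps, so truncated background sequences do not create false
    terminal insertions.
    """

    bg_gap_frac: float = 1.0
    merge_gap: int = 0
    min_len: int = 3
    ignore_terminal_gaps: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.bg_gap_frac <= 1):
            raise ValueError("bg_gap_frac must be in (0, 1]")
        if self.merge_gap < 0 or self.min_len < 1:
            raise ValueError("merge_gap >= 0 and min_len >= 1 required")


def _char_matrix(aln: Alignment, taxa: Sequence[str]) -> np.ndarray:
    return np.array([list(aln.row(t)) for t in taxa])


def classify_columns(
    aln: Alignment,
    partition: FocalPartition,
    bg_gap_frac: float = 1.0,
    ignore_terminal_gaps: bool = False,
) -> np.ndarray:
    """Label each column as insertion-candidate (True) or other (False).

    A column is a candidate iff at least one focal taxon carries a residue
    and the fraction of background taxa gapped there is >= ``bg_gap_frac``.
    With ``ignore_terminal_gaps`` a background taxon's terminal gap runs
    are removed from both numerator and denominator of that fraction.
    """
    partition.validate(aln)
    if not (0 < bg_gap_frac <= 1):
        raise ValueError("bg_gap_frac must be in (0, 1]")
    focal = sorted(partition.focal)
    background = sorted(partition.background)
    fm = _char_matrix(aln, focal)
    bm = _char_matrix(aln, background)
    focal_has_residue = (fm != GAP).any(axis=0)
    bg_is_gap = bm == GAP
    if ignore_terminal_gaps:
        scored = np.ones_like(bg_is_gap, dtype=bool)
        for i, taxon in enumerate(background):
            row = aln.row(taxon)
            lead = len(row) - len(row.lstrip(GAP))
            trail = len(row) - len(row.rstrip(GAP))
            if lead:
                scored[i, :lead] = False
            if trail:
                scored[i, len(row) - trail:] = False
        n_scored = scored.sum(axis=0)
        n_gap = (bg_is_gap & scored).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_scored > 0, n_gap / np.maximum(n_scored, 1), 0.0)
    else:
        frac = bg_is_gap.mean(axis=0)
    return focal_has_residue & (frac >= bg_gap_frac)


def _candidate_runs(candidate: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Maximal candidate runs, then merge runs separated by <= merge_gap."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, c in enumerate(candidate):
        if c and start is None:
            start = i
        elif not c and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(candidate)))
    if merge_gap <= 0 or len(runs) < 2:
        return runs
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe <= merge_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def map_columns_to_residues(
    aln: Alignment, taxon: str, col_interval: tuple[int, int]
) -> tuple[int, int]:
    """Map a half-open column interval to the taxon's ungapped residues.

    Returns the half-open residue interval counting only non-gap
    characters of the taxon; the interval may be empty (start == end) if
    the taxon is entirely gapped across the columns.
    """
    s, e = col_interval
    row = aln.row(taxon)
    if not (0 <= s <= e <= aln.n_cols):
        raise OutOfRangeError(
            f"{aln.id}: column interval [{s},{e}) outside [0,{aln.n_cols})"
        )
    res_start = len(row[:s]) - row[:s].count(GAP)
    res_end = res_start + len(row[s:e]) - row[s:e].count(GAP)
    return (res_start, res_end)


def detect_insertion_blocks(
    aln: Alignment,
    partition: FocalPartition,
    params: DetectionParams = DetectionParams(),
) -> list[InsertionBlock]:
    """Call per-focal-taxon insertion blocks in one alignment.

    Candidate runs are computed once for the partition; per focal taxon a
    block is emitted for each (merged) run in which that taxon has at
    least ``min_len`` residues in candidate columns. Blocks are sorted by
    (taxon, col_start).
    """
    candidate = classify_columns(
        aln,
        partition,
        bg_gap_frac=params.bg_gap_frac,
        ignore_terminal_gaps=params.ignore_terminal_gaps,
    )
    runs = _candidate_runs(candidate, params.merge_gap)
    blocks: list[InsertionBlock] = []
    for taxon in sorted(partition.focal):
        row = aln.row(taxon)
        for s, e in runs:
            n_res = sum(
                1 for i in range(s, e) if candidate[i] and row[i] != GAP
            )
            if n_res < params.min_len:
                continue
            res_start, res_end = map_columns_to_residues(aln, taxon, (s, e))
            blocks.append(
                InsertionBlock(
                    orthogroup=aln.id,
                    taxon=taxon,
                    col_start=s,
                    col_end=e,
                    res_start=res_start,
                    res_end=res_end,
                    length_res=n_res,
                    cand_cols=int(candidate[s:e].sum()),
                )
            )
    blocks.sort(key=lambda b: (b.taxon, b.col_start))
    return blocks


def insertion_fraction(
    aln: Alignment, blocks: Sequence[InsertionBlock], taxon: str
) -> FractionRecord:
    """Fraction of alignment columns inside one taxon's insertion blocks.

    Only insertion-candidate columns count toward the numerator (columns
    merged over inside a block do not); the denominator is the full
    alignment width.
    """
    if taxon not in aln.taxa:
        raise UnknownTaxonError(f"{aln.id}: taxon {taxon!r} not in alignment")
    inserted = 0
    for b in blocks:
        if b.orthogroup != aln.id:
            raise ForeignBlocksError(
                f"block from {b.orthogroup!r} applied to alignment {aln.id!r}"
            )
        if b.taxon == taxon:
            inserted += b.cand_cols
    return FractionRecord(
        orthogroup=aln.id,
        taxon=taxon,
        inserted_cols=inserted,
        total_cols=aln.n_cols,
    )


def peptide_coverage(
    protein: str,
    intervals: Sequence[tuple[int, int]],
    peptides: PeptideSet,
    il_equiv: bool = False,
) -> list[dict]:
    """Check which insertion intervals are covered by observed peptides.

    A peptide covers an interval iff some exact occurrence of it in the
    protein overlaps the interval by at least one residue; all (possibly
    overlapping) occurrences are considered. With ``il_equiv`` isoleucine
    and leucine are treated as identical, the usual mass-spectrometry
    convention since they are isobaric.

    Returns one dict per interval with keys ``interval``, ``covered`` and
    ``peptides`` (the covering peptides, in input order).
    """
    protein = protein.upper()
    n = len(protein)
    for s, e in intervals:
        if not (0 <= s <= e <= n):
            raise IntervalOutOfRangeError(
                f"interval [{s},{e}) outside protein of length {n}"
            )

    def norm(seq: str) -> str:
        return seq.replace("L", "I") if il_equiv else seq

    hay = norm(protein)
    occurrences: dict[str, list[tuple[int, int]]] = {}
    for pep in peptides.peptides:
        needle = norm(pep)
        occ = []
        start = 0
        while True:
            idx = hay.find(needle, start)
            if idx < 0:
                break
            occ.append((idx, idx + len(needle)))
            start = idx + 1  # allow overlapping occurrences
        occurrences[pep] = occ

    out = []
    for s, e in intervals:
        covering = [
            pep
            for pep in peptides.peptides
            if any(os < e and s < oe for os, oe in occurrences[pep])
        ]
        out.append(
            {"interval": (s, e), "covered": bool(covering), "peptides": covering}
        )
    return out
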