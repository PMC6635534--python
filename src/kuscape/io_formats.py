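"""Readers, writers and the validated in-memory data model.

External formats handled here: aligned FASTA (gap ``-``), Newick species
trees, tab-separated tables (UTF-8, ``#``-prefixed comment lines ignored)
and the insertion-block TSV dialect.

Coordinate convention: everything in memory is 0-based, half-open, for both
alignment columns and ungapped residue positions. Everything on disk is
1-based, inclusive, which is what most biologists expect to see in a table.
The two conversions are exact inverses of each other.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import dendropy

from .errors import (
    DuplicateSpeciesError,
    DuplicateTipError,
    EmptyFileError,
    IllegalCharacterError,
    MissingColumnError,
    NewickParseError,
    NonPositiveSizeError,
    RaggedAlignmentError,
)

#: Canonical order of the 20 standard amino acids used everywhere in the
#: package (composition vectors, enrichment tables, simulators).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Full residue alphabet accepted after normalization: the 20 standard
#: amino acids plus 'X' for an unknown residue. 'X' occupies an alignment
#: column like any residue; it is excluded from composition statistics.
RESIDUE_ALPHABET = frozenset(AMINO_ACIDS) | {"X"}

GAP = "-"

_ALLOWED = RESIDUE_ALPHABET | {GAP}

PROFILE_COLUMNS = (
    "species",
    "clade",
    "lifestyle",
    "genome_size_mb",
    "ku70",
    "ku80",
    "lig4",
)

COMPONENTS = ("ku70", "ku80", "lig4")

LIFESTYLES = ("parasite", "free_living", "unknown")

BLOCKS_TSV_COLUMNS = (
    "orthogroup",
    "taxon",
    "col_start",
    "col_end",
    "res_start",
    "res_end",
    "length_res",
    "cand_cols",
)


# ----------------------------------------------------------------------
# Alignment
# ----------------------------------------------------------------------


@dataclass
class Alignment:
    """A rectangular gapped protein multiple sequence alignment.

    Parameters
    ----------
    id
        Orthogroup identifier.
    taxa
        Ordered taxon ids, unique within the alignment.
    rows
        One gapped sequence per taxon, all of identical length, drawn from
        the 20 standard amino acids, ``X`` and ``-``.
    """

    id: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise RaggedAlignmentError(
                f"{self.id}: {len(self.taxa)} taxa but {len(self.rows)} rows"
            )
        if not self.rows:
            raise EmptyFileError(f"{self.id}: alignment has no rows")
        if len(set(self.taxa)) != len(self.taxa):
            seen: set[str] = set()
            dup = next(t for t in self.taxa if t in seen or seen.add(t))
            raise DuplicateSpeciesError(f"{self.id}: duplicated taxon id {dup!r}")
        n = len(self.rows[0])
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) != n:
                raise RaggedAlignmentError(
                    f"{self.id}: row {taxon!r} has length {len(row)}, expected {n}"
                )
            bad = set(row) - _ALLOWED
            if bad:
                raise IllegalCharacterError(
                    f"{self.id}: row {taxon!r} contains illegal symbol(s) "
                    f"{sorted(bad)!r}"
                )
        if n < 1:
            raise RaggedAlignmentError(f"{self.id}: zero-length alignment")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        from .errors import UnknownTaxonError

        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise UnknownTaxonError(
                f"{self.id}: taxon {taxon!r} not in alignment"
            ) from None

    def ungapped(self, taxon: str) -> str:
        """The taxon's sequence with all gap characters removed."""
        return self.row(taxon).replace(GAP, "")


def normalize_sequence(seq: str) -> str:
    """Uppercase and map ``.`` gaps to ``-``; validation happens later."""
    return seq.upper().replace(".", GAP)


def read_alignment(path: str | Path, id: str | None = None) -> Alignment:
    """Read one aligned FASTA file into a normalized :class:`Alignment`.

    Lowercase letters are uppercased and ``.`` is stored as ``-``. The
    orthogroup id defaults to the file stem.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise EmptyFileError(f"{path}: need at least 2 FASTA records, got {len(records)}")
    taxa = [r.id for r in records]
    rows = [normalize_sequence(str(r.seq)) for r in records]
    return Alignment(id=id or path.stem, taxa=taxa, rows=rows)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as aligned FASTA (one line per sequence)."""
    records = [
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(aln.taxa, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta-2line")


# ----------------------------------------------------------------------
# Phyletic profile
# ----------------------------------------------------------------------


@dataclass
class PhyleticProfile:
    """Species-by-component presence matrix joined to genome metadata.

    ``df`` has the columns ``species, clade, lifestyle, genome_size_mb,
    ku70, ku80, lig4``. Component calls are pandas nullable ``Int64`` so
    that a missing call (absence of evidence in the source database) stays
    NA and is never silently coerced to 0.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PROFILE_COLUMNS if c not in self.df.columns]
        if missing:
            raise MissingColumnError(f"profile table lacks column(s) {missing}")
        df = self.df.copy()
        df["species"] = df["species"].astype(str)
        dup = df["species"][df["species"].duplicated()]
        if not dup.empty:
            raise DuplicateSpeciesError(f"duplicated species id(s): {sorted(set(dup))}")
        df["genome_size_mb"] = pd.to_numeric(df["genome_size_mb"], errors="coerce")
        bad = df["genome_size_mb"].notna() & (df["genome_size_mb"] <= 0)
        if bad.any():
            raise NonPositiveSizeError(
                f"non-positive genome size for {df.loc[bad, 'species'].tolist()}"
            )
        for comp in COMPONENTS:
            col = pd.to_numeric(df[comp], errors="coerce").astype("Int64")
            ok = col.isna() | col.isin([0, 1])
            if not ok.all():
                raise MissingColumnError(
                    f"column {comp!r} must contain only 0, 1 or NA"
                )
            df[comp] = col
        df["lifestyle"] = df["lifestyle"].fillna("unknown").astype(str)
        object.__setattr__(self, "df", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> list[str]:
        return self.df["species"].tolist()


def read_profile_table(path: str | Path) -> PhyleticProfile:
    """Read a phyletic profile TSV (``NA`` / empty cells stay missing)."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"species": str, "clade": str, "lifestyle": str},
        na_values=["NA", "na", ""],
        keep_default_na=True,
    )
    if df.empty and df.columns.empty:
        raise EmptyFileError(f"{path}: empty profile table")
    return PhyleticProfile(df)


def write_profile_table(profile: PhyleticProfile, path: str | Path) -> None:
    profile.df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ----------------------------------------------------------------------
# Species tree
# ----------------------------------------------------------------------


@dataclass
class SpeciesTree:
    """A rooted species tree with uniquely labeled tips.

    Thin wrapper over a :class:`dendropy.Tree`; polytomies are allowed.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            seen: set[str] = set()
            dup = next(t for t in labels if t in seen or seen.add(t))
            raise DuplicateTipError(f"duplicated tip label {dup!r}")

    @property
    def tip_labels(self) -> list[str]:
        return [
            leaf.taxon.label for leaf in self.tree.leaf_node_iter() if leaf.taxon
        ]

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(path_or_string: str | Path) -> SpeciesTree:
    """Parse a single rooted Newick tree from a file or a literal string."""
    src = str(path_or_string)
    if src.lstrip().startswith("("):
        data = src
    else:
        data = Path(src).read_text()
    if not data.strip():
        raise EmptyFileError("empty Newick input")
    try:
        tree = dendropy.Tree.get(
            data=data, schema="newick", suppress_internal_node_taxa=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise DuplicateTipError(f"duplicated tip label in Newick: {exc}") from exc
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    return SpeciesTree(tree)


def write_newick(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


# ----------------------------------------------------------------------
# Peptides
# ----------------------------------------------------------------------

MIN_PEPTIDE_LEN = 5


@dataclass
class PeptideSet:
    """Peptides observed for one protein (e.g. by mass spectrometry)."""

    protein_id: str
    peptides: list[str]

    def __post_init__(self) -> None:
        cleaned = []
        for pep in self.peptides:
            pep = pep.strip().upper()
            if len(pep) < MIN_PEPTIDE_LEN:
                raise IllegalCharacterError(
                    f"{self.protein_id}: peptide {pep!r} shorter than "
                    f"{MIN_PEPTIDE_LEN} residues"
                )
            bad = set(pep) - set(AMINO_ACIDS)
            if bad:
                raise IllegalCharacterError(
                    f"{self.protein_id}: peptide {pep!r} has illegal symbol(s) {sorted(bad)}"
                )
            cleaned.append(pep)
        self.peptides = cleaned


def read_peptides_tsv(path: str | Path) -> list[PeptideSet]:
    """Read a two-column TSV ``protein_id<TAB>peptide`` into peptide sets."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("protein_id", "peptide"):
        if col not in df.columns:
            raise MissingColumnError(f"{path}: peptide table lacks column {col!r}")
    out = []
    for pid, grp in df.groupby("protein_id", sort=True):
        out.append(PeptideSet(protein_id=str(pid), peptides=grp["peptide"].tolist()))
    return out


# ----------------------------------------------------------------------
# Insertion blocks
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class InsertionBlock:
    """A maximal focal-lineage-specific inserted region for one taxon.

    Column and residue coordinates are 0-based half-open. ``length_res``
    counts the focal taxon's residues in *insertion-candidate* columns of
    the block, and ``cand_cols`` the candidate columns themselves; with a
    nonzero merge gap a block may additionally span interior non-candidate
    columns, so ``res_end - res_start >= length_res`` with equality
    whenever no columns were merged over.
    """

    orthogroup: str
    taxon: str
    col_start: int
    col_end: int
    res_start: int
    res_end: int
    length_res: int
    cand_cols: int

    def __post_init__(self) -> None:
        if not (0 <= self.col_start < self.col_end):
            raise ValueError(f"bad column interval [{self.col_start},{self.col_end})")
        if not (0 <= self.res_start <= self.res_end):
            raise ValueError(f"bad residue interval [{self.res_start},{self.res_end})")
        if self.res_end - self.res_start < self.length_res:
            raise ValueError("residue interval shorter than length_res")

    @property
    def merged_span_cols(self) -> int:
        """Columns spanned after merging (block width in columns)."""
        return self.col_end - self.col_start


def write_blocks_tsv(blocks: Sequence[InsertionBlock], path: str | Path) -> None:
    """Write blocks as TSV with 1-based inclusive coordinates.

    An empty block list yields a header-only file. Half-open 0-based
    ``[s, e)`` becomes ``s+1 .. e`` on disk; an empty residue interval is
    written with ``res_start > res_end``.
    """
    rows = [
        {
            "orthogroup": b.orthogroup,
            "taxon": b.taxon,
            "col_start": b.col_start + 1,
            "col_end": b.col_end,
            "res_start": b.res_start + 1,
            "res_end": b.res_end,
            "length_res": b.length_res,
            "cand_cols": b.cand_cols,
        }
        for b in blocks
    ]
    df = pd.DataFrame(rows, columns=list(BLOCKS_TSV_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_blocks_tsv(path: str | Path) -> list[InsertionBlock]:
    """Read a blocks TSV back into memory (inverse of :func:`write_blocks_tsv`)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in BLOCKS_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: blocks table lacks column(s) {missing}")
    blocks = []
    for rec in df.itertuples(index=False):
        blocks.append(
            InsertionBlock(
                orthogroup=str(rec.orthogroup),
                taxon=str(rec.taxon),
                col_start=int(rec.col_start) - 1,
                col_end=int(rec.col_end),
                res_start=int(rec.res_start) - 1,
                res_end=int(rec.res_end),
                length_res=int(rec.length_res),
                cand_cols=int(rec.cand_cols),
            )
        )
    return blocks
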