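"""Statistical layer of the insertion analysis.

Covers amino-acid composition enrichment of inserted vs non-inserted
sequence, cross-taxon similarity of enrichment patterns, the paired
comparison of per-orthogroup insertion fractions between a focal taxon
and a reference taxon, divergence of insertion-flanking regions, and the
correlation between alignment conservation and insertion load.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    ConstantInputError,
    EmptyPoolError,
    InsufficientOverlapError,
    NoDistalColumnsError,
    NoFlankColumnsError,
    TooFewAlignmentsError,
    TooFewPairsError,
)
from .insertions import FocalPartition
from .io_formats import AMINO_ACIDS, GAP, Alignment, InsertionBlock

__all__ = [
    "CompositionTable",
    "PairedComparison",
    "FlankDivergence",
    "composition_enrichment",
    "enrichment_similarity",
    "compare_fraction_paired",
    "flank_divergence",
    "conservation_vs_insertion",
    "alignment_conservation",
    "g_test_2x2",
]

#: Sentinel serialized for an infinite ratio (e.g. mismatches only in flanks).
INF_SENTINEL = float("inf")


# ----------------------------------------------------------------------
# G-test
# ----------------------------------------------------------------------


def g_test_2x2(table: np.ndarray) -> tuple[float, float]:
    """Log-likelihood-ratio (G) test of independence for a 2x2 table.

    Zero cells contribute nothing to G (0*log 0 := 0); a zero row or
    column margin makes the test undefined and returns (0.0, nan).
    """
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        return 0.0, float("nan")
    expected = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * terms.sum()
    g = max(g, 0.0)  # guard tiny negative round-off
    return float(g), float(sps.chi2.sf(g, df=1))


def _g_test_2xk(table: np.ndarray) -> tuple[float, float]:
    obs = np.asarray(table, dtype=float)
    keep = obs.sum(axis=0) > 0
    obs = obs[:, keep]
    if obs.shape[1] < 2 or (obs.sum(axis=1) == 0).any():
        return 0.0, float("nan")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    expected = np.outer(row, col) / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = max(2.0 * terms.sum(), 0.0)
    df = obs.shape[1] - 1
    return float(g), float(sps.chi2.sf(g, df=df))


# ----------------------------------------------------------------------
# Composition enrichment
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class CompositionTable:
    """Amino-acid composition of one taxon's insertions vs the rest.

    ``enrichment[aa]`` is the ratio of relative frequencies
    (insertion / background); it is NaN (undefined) when the amino acid
    never occurs in the background pool, and 0 when it occurs only there.
    P-values come from per-amino-acid 2x2 G-tests (this residue vs the
    other 19, insertion vs background), q-values from Benjamini-Hochberg;
    an omnibus 2xK G-test over the whole composition is carried alongside.
    'X' residues are excluded from both pools.
    """

    taxon: str
    counts_insertion: dict[str, int]
    counts_background: dict[str, int]
    enrichment: dict[str, float]
    p_values: dict[str, float]
    q_values: dict[str, float]
    omnibus_g: float
    omnibus_p: float

    @property
    def n_insertion(self) -> int:
        return sum(self.counts_insertion.values())

    @property
    def n_background(self) -> int:
        return sum(self.counts_background.values())


def _count_pools(
    alignments: Sequence[Alignment],
    blocks: Sequence[InsertionBlock],
    taxon: str,
) -> tuple[np.ndarray, np.ndarray]:
    by_og: dict[str, list[InsertionBlock]] = {}
    for b in blocks:
        if b.taxon == taxon:
            by_og.setdefault(b.orthogroup, []).append(b)
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    ci = np.zeros(20, dtype=int)
    cb = np.zeros(20, dtype=int)
    for aln in alignments:
        if taxon not in aln.taxa:
            continue
        row = aln.row(taxon)
        inside = np.zeros(aln.n_cols, dtype=bool)
        for b in by_og.get(aln.id, []):
            inside[b.col_start : b.col_end] = True
        for j, ch in enumerate(row):
            if ch == GAP or ch not in idx:
                continue  # gaps and 'X' excluded
            if inside[j]:
                ci[idx[ch]] += 1
            else:
                cb[idx[ch]] += 1
    return ci, cb


def composition_enrichment(
    alignments: Sequence[Alignment],
    blocks: Sequence[InsertionBlock],
    taxon: str,
) -> CompositionTable:
    """Per-amino-acid enrichment of a taxon's insertions over its background."""
    ci, cb = _count_pools(alignments, blocks, taxon)
    n_ins, n_bg = int(ci.sum()), int(cb.sum())
    if n_ins == 0:
        raise EmptyPoolError(f"{taxon}: no insertion residues to analyse")
    enrichment: dict[str, float] = {}
    p_values: dict[str, float] = {}
    for i, aa in enumerate(AMINO_ACIDS):
        if n_bg == 0 or cb[i] == 0:
            enr = float("nan")  # undefined: background frequency is zero
        else:
            enr = (ci[i] / n_ins) / (cb[i] / n_bg)
        enrichment[aa] = enr
        g, p = g_test_2x2(
            [[ci[i], n_ins - ci[i]], [cb[i], n_bg - cb[i]]]
        )
        p_values[aa] = p
    defined = [aa for aa in AMINO_ACIDS if not math.isnan(p_values[aa])]
    q_values = {aa: float("nan") for aa in AMINO_ACIDS}
    if defined:
        q = sps.false_discovery_control([p_values[aa] for aa in defined])
        q_values.update({aa: float(v) for aa, v in zip(defined, q)})
    og, op = _g_test_2xk(np.vstack([ci, cb]))
    return CompositionTable(
        taxon=taxon,
        counts_insertion={aa: int(ci[i]) for i, aa in enumerate(AMINO_ACIDS)},
        counts_background={aa: int(cb[i]) for i, aa in enumerate(AMINO_ACIDS)},
        enrichment=enrichment,
        p_values=p_values,
        q_values=q_values,
        omnibus_g=og,
        omnibus_p=op,
    )


def enrichment_similarity(
    tables: Sequence[CompositionTable], min_shared: int = 5
) -> pd.DataFrame:
    """Pairwise Pearson correlation of log2 enrichment between taxa.

    Only amino acids with a finite positive enrichment in both tables
    enter a pair's correlation; fewer than ``min_shared`` such residues
    is an error rather than a silent unstable estimate.
    """
    if len(tables) < 2:
        raise InsufficientOverlapError("need at least two composition tables")
    taxa = [t.taxon for t in tables]
    mat = np.eye(len(tables))
    for (i, ta), (j, tb) in itertools.combinations(enumerate(tables), 2):
        shared = [
            aa
            for aa in AMINO_ACIDS
            if _finite_pos(ta.enrichment[aa]) and _finite_pos(tb.enrichment[aa])
        ]
        if len(shared) < min_shared:
            raise InsufficientOverlapError(
                f"{ta.taxon} vs {tb.taxon}: only {len(shared)} shared "
                f"defined-enrichment amino acids (need {min_shared})"
            )
        xa = np.log2([ta.enrichment[aa] for aa in shared])
        xb = np.log2([tb.enrichment[aa] for aa in shared])
        r = float(sps.pearsonr(xa, xb).statistic)
        mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=taxa, columns=taxa)


def _finite_pos(x: float) -> bool:
    return math.isfinite(x) and x > 0


# ----------------------------------------------------------------------
# Paired fraction comparison
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class PairedComparison:
    """Wilcoxon signed-rank comparison of per-orthogroup insertion fractions."""

    focal_taxon: str
    reference_taxon: str
    n_alignments: int
    fractions_focal: tuple[float, ...]
    fractions_reference: tuple[float, ...]
    statistic: float  # signed-rank sum (W+ - W-); sign flips with the roles
    p_value: float
    test_name: str


#: Number of nonzero differences up to which the Wilcoxon p is exact
#: (exact only without tied absolute differences).
WILCOXON_EXACT_MAX_N = 25


def compare_fraction_paired(
    fractions_focal: Mapping[str, float],
    fractions_reference: Mapping[str, float],
    focal_taxon: str = "focal",
    reference_taxon: str = "reference",
    min_pairs: int = 3,
) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on paired insertion fractions.

    Pairs are matched by orthogroup id; zero differences are dropped
    (Wilcoxon convention). The p-value is exact for up to
    ``WILCOXON_EXACT_MAX_N`` untied nonzero differences, otherwise a
    normal approximation with continuity and tie correction is used.
    """
    shared = sorted(set(fractions_focal) & set(fractions_reference))
    if len(shared) < min_pairs:
        raise TooFewPairsError(
            f"only {len(shared)} shared orthogroups (need >= {min_pairs})"
        )
    x = np.array([fractions_focal[k] for k in shared], dtype=float)
    y = np.array([fractions_reference[k] for k in shared], dtype=float)
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        return PairedComparison(
            focal_taxon=focal_taxon,
            reference_taxon=reference_taxon,
            n_alignments=len(shared),
            fractions_focal=tuple(x),
            fractions_reference=tuple(y),
            statistic=0.0,
            p_value=1.0,
            test_name="wilcoxon_all_zero",
        )
    ranks = sps.rankdata(np.abs(nz))
    statistic = float(np.sum(np.sign(nz) * ranks))
    has_ties = len(np.unique(np.abs(nz))) < nz.size
    if nz.size <= WILCOXON_EXACT_MAX_N and not has_ties:
        res = sps.wilcoxon(nz, zero_method="wilcox", method="exact")
        name = "wilcoxon_exact"
    else:
        res = sps.wilcoxon(
            nz, zero_method="wilcox", method="approx", correction=True
        )
        name = "wilcoxon_normal_approx"
    return PairedComparison(
        focal_taxon=focal_taxon,
        reference_taxon=reference_taxon,
        n_alignments=len(shared),
        fractions_focal=tuple(x),
        fractions_reference=tuple(y),
        statistic=statistic,
        p_value=float(res.pvalue),
        test_name=name,
    )


# ----------------------------------------------------------------------
# Flank divergence
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class FlankDivergence:
    """Mismatch rates near insertion boundaries vs away from them.

    ``ratio`` is flank/distal; both rates zero gives 1.0 by convention,
    and mismatches found only in the flanks give +inf.
    """

    flank_mismatch_rate: float
    distal_mismatch_rate: float
    ratio: float
    n_flank_cols: int
    n_distal_cols: int
    flank_width: int


def flank_divergence(
    aln: Alignment,
    blocks: Sequence[InsertionBlock],
    flank_width: int = 5,
    partition: FocalPartition | None = None,
) -> FlankDivergence:
    """Compare focal-background mismatch rates in flank vs distal columns.

    Flank columns lie within ``flank_width`` columns of any block
    boundary (outside the blocks themselves); distal columns are all
    other columns outside blocks. Only fully gap-free columns are scored,
    and the rate is the fraction of (focal, background) residue pairs
    that differ. Without an explicit partition the focal set defaults to
    the taxa carrying blocks and the background to everything else.
    """
    if flank_width < 1:
        raise ValueError("flank_width must be >= 1")
    if partition is None:
        focal = sorted({b.taxon for b in blocks})
        background = sorted(set(aln.taxa) - set(focal))
        if not focal or not background:
            raise NoFlankColumnsError(
                "cannot infer a focal/background partition from the blocks"
            )
    else:
        partition.validate(aln)
        focal = sorted(partition.focal)
        background = sorted(partition.background)

    inside = np.zeros(aln.n_cols, dtype=bool)
    flank = np.zeros(aln.n_cols, dtype=bool)
    for b in blocks:
        inside[b.col_start : b.col_end] = True
        lo = max(0, b.col_start - flank_width)
        hi = min(aln.n_cols, b.col_end + flank_width)
        flank[lo : b.col_start] = True
        flank[b.col_end : hi] = True
    flank &= ~inside

    rows = np.array([list(r) for r in aln.rows])
    gap_free = (rows != GAP).all(axis=0)
    fm = np.array([list(aln.row(t)) for t in focal])
    bm = np.array([list(aln.row(t)) for t in background])

    def pair_mismatch(cols: np.ndarray) -> tuple[float, int]:
        sel = np.flatnonzero(cols)
        if sel.size == 0:
            return float("nan"), 0
        f = fm[:, sel]
        b = bm[:, sel]
        diff = f[:, None, :] != b[None, :, :]
        return float(diff.mean()), int(sel.size)

    flank_rate, n_flank = pair_mismatch(flank & gap_free)
    distal_rate, n_distal = pair_mismatch(~flank & ~inside & gap_free)
    if n_flank == 0:
        raise NoFlankColumnsError("no gap-free flank columns")
    if n_distal == 0:
        raise NoDistalColumnsError("no gap-free distal columns")
    if flank_rate == 0 and distal_rate == 0:
        ratio = 1.0
    elif distal_rate == 0:
        ratio = INF_SENTINEL
    else:
        ratio = flank_rate / distal_rate
    return FlankDivergence(
        flank_mismatch_rate=flank_rate,
        distal_mismatch_rate=distal_rate,
        ratio=ratio,
        n_flank_cols=n_flank,
        n_distal_cols=n_distal,
        flank_width=flank_width,
    )


# ----------------------------------------------------------------------
# Conservation vs insertion load
# ----------------------------------------------------------------------


def alignment_conservation(aln: Alignment, candidate: np.ndarray) -> float:
    """Mean pairwise identity over non-candidate, gap-free columns.

    Returns NaN when no column qualifies (e.g. everything inserted).
    """
    rows = np.array([list(r) for r in aln.rows])
    gap_free = (rows != GAP).all(axis=0)
    sel = np.flatnonzero(gap_free & ~np.asarray(candidate, dtype=bool))
    if sel.size == 0 or len(aln.taxa) < 2:
        return float("nan")
    sub = rows[:, sel]
    idents = [
        float((sub[i] == sub[j]).mean())
        for i, j in itertools.combinations(range(len(aln.taxa)), 2)
    ]
    return float(np.mean(idents))


def conservation_vs_insertion(
    records: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Spearman correlation between conservation and insertion fraction.

    ``records`` holds one (conservation, fraction) pair per alignment.
    Returns (rho, two-sided p).
    """
    if len(records) < 4:
        raise TooFewAlignmentsError(
            f"need >= 4 alignments, got {len(records)}"
        )
    cons = np.array([r[0] for r in records], dtype=float)
    frac = np.array([r[1] for r in records], dtype=float)
    if np.unique(cons).size == 1 or np.unique(frac).size == 1:
        raise ConstantInputError("conservation or fraction vector is constant")
    res = sps.spearmanr(cons, frac)
    return float(res.statistic), float(res.pvalue)
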