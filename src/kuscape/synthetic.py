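"""Synthetic-data generators with known ground truth.

Two generators emulate the pipeline's inputs:

* :func:`simulate_orthogroup` — an orthologous protein alignment in which
  the focal lineage (and optionally a reference taxon) acquired short
  insertions; the true alignment is emitted directly from the known
  homology, so detection performance is measured without aligner error.
* :func:`simulate_phyletic_table` — a species table whose probability of
  having lost all three C-NHEJ components follows a logistic model in
  log10 genome size, giving a controllable size-loss association.

All randomness flows from one :class:`numpy.random.Generator` seeded from
a single integer, so every output is reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParamsError
from .io_formats import (
    AMINO_ACIDS,
    GAP,
    Alignment,
    InsertionBlock,
    PhyleticProfile,
    SpeciesTree,
    read_newick,
)

__all__ = [
    "OrthogroupSimParams",
    "PhyleticSimParams",
    "DEFAULT_INSERTION_FREQS",
    "simulate_orthogroup",
    "simulate_phyletic_table",
    "simulate_species_tree",
    "synthetic_census_profile",
    "rates_for_pooled_fractions",
    "expected_pooled_fraction",
]


def _make_insertion_freqs() -> np.ndarray:
    # Mildly skewed toward small/polar residues, emulating the
    # low-complexity character typical of young inserted sequence.
    weights = {
        "A": 2.0, "S": 1.8, "G": 1.6, "P": 1.5, "T": 1.4, "E": 1.3, "Q": 1.2,
        "W": 0.4, "C": 0.5, "F": 0.6, "Y": 0.6, "M": 0.7,
    }
    w = np.array([weights.get(aa, 1.0) for aa in AMINO_ACIDS], dtype=float)
    return w / w.sum()


#: Default amino-acid frequency vector for simulated insertions.
DEFAULT_INSERTION_FREQS = _make_insertion_freqs()


@dataclass(frozen=True)
class OrthogroupSimParams:
    """Parameters of the orthogroup/insertion simulator.

    ``ins_rate`` is the expected number of focal-lineage insertion events
    per ancestral site (events shared by the whole focal clade);
    ``ref_ins_rate`` adds private insertions on the reference taxon's
    terminal branch. Insertion lengths are geometric with mean
    ``ins_mean_len`` (support >= 1). ``subst_prob`` is the per-site
    substitution probability on each terminal branch; within
    ``flank_width`` ancestral sites of an insertion point it is
    multiplied by ``flank_mult`` for every taxon, emulating the elevated
    divergence seen around indels.
    """

    length: int = 1000
    focal_taxa: tuple[str, ...] = ("jacA", "jacB")
    background_taxa: tuple[str, ...] = ("Tbrucei", "Tcruzi", "Lmajor", "Cfasciculata")
    reference: str | None = "Tbrucei"
    subst_prob: float = 0.05
    ins_rate: float = 0.02
    ref_ins_rate: float = 0.0
    ins_mean_len: float = 8.0
    ins_freqs: tuple[float, ...] = tuple(DEFAULT_INSERTION_FREQS)
    flank_mult: float = 1.0
    flank_width: int = 5
    orthogroup: str = "OG0000001"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise InvalidParamsError("length must be >= 1")
        if not self.focal_taxa or not self.background_taxa:
            raise InvalidParamsError("need at least one focal and one background taxon")
        names = list(self.focal_taxa) + list(self.background_taxa)
        if len(set(names)) != len(names):
            raise InvalidParamsError("taxon names must be unique and disjoint")
        if self.reference is not None and self.reference not in self.background_taxa:
            raise InvalidParamsError("reference must be one of the background taxa")
        if not (0 <= self.subst_prob < 1):
            raise InvalidParamsError("subst_prob must be in [0, 1)")
        if self.ins_rate < 0 or self.ref_ins_rate < 0:
            raise InvalidParamsError("insertion rates must be >= 0")
        if self.ins_mean_len < 1:
            raise InvalidParamsError("ins_mean_len must be >= 1")
        freqs = np.asarray(self.ins_freqs, dtype=float)
        if freqs.shape != (20,) or (freqs < 0).any() or not np.isclose(freqs.sum(), 1.0):
            raise InvalidParamsError("ins_freqs must be a 20-vector summing to 1")
        if self.flank_mult < 0 or self.flank_width < 0:
            raise InvalidParamsError("flank_mult and flank_width must be >= 0")
        if self.ref_ins_rate > 0 and self.reference is None:
            raise InvalidParamsError("ref_ins_rate > 0 requires a reference taxon")


def _mutate(seq: np.ndarray, p: np.ndarray | float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p, uniform over the 19 others."""
    out = seq.copy()
    mask = rng.random(seq.size) < p
    n = int(mask.sum())
    if n:
        out[mask] = (seq[mask] + 1 + rng.integers(0, 19, size=n)) % 20
    return out


def _draw_events(
    rng: np.random.Generator, rate: float, length: int, mean_len: float,
    freqs: np.ndarray,
) -> list[tuple[int, np.ndarray]]:
    """Events as (ancestral insertion site, residue int array), distinct sites."""
    if rate <= 0:
        return []
    k = int(rng.poisson(rate * length))
    k = min(k, length + 1)
    if k == 0:
        return []
    sites = np.sort(rng.choice(length + 1, size=k, replace=False))
    lens = rng.geometric(1.0 / mean_len, size=k)
    return [
        (int(s), rng.choice(20, size=int(l), p=freqs)) for s, l in zip(sites, lens)
    ]


def simulate_orthogroup(
    params: OrthogroupSimParams,
    rng: np.random.Generator | None = None,
) -> tuple[Alignment, list[InsertionBlock]]:
    """Simulate one orthogroup alignment plus its true insertion blocks.

    The ancestral sequence is uniform over the 20 amino acids; focal
    insertions are drawn once per event and shared (with independent
    terminal-branch substitutions) by every focal taxon; background taxa
    carry gaps across focal insertion columns, and vice versa for
    reference-private insertions. The returned blocks carry exact column
    and residue coordinates for every focal taxon (and for the reference
    taxon when it has private insertions).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    L = params.length
    freqs = np.asarray(params.ins_freqs, dtype=float)
    anc = rng.integers(0, 20, size=L)

    focal_events = _draw_events(rng, params.ins_rate, L, params.ins_mean_len, freqs)
    ref_events = _draw_events(rng, params.ref_ins_rate, L, params.ins_mean_len, freqs)

    # per-ancestral-site substitution probability, elevated near insertions
    d_anc = np.full(L, params.subst_prob)
    if params.flank_mult != 1.0 and params.flank_width > 0:
        elevated = np.zeros(L, dtype=bool)
        for site, _ in focal_events + ref_events:
            lo = max(0, site - params.flank_width)
            hi = min(L, site + params.flank_width)
            elevated[lo:hi] = True
        d_anc[elevated] = np.minimum(params.subst_prob * params.flank_mult, 0.95)

    # column layout: at each ancestral site, focal events then ref events,
    # then the ancestral column itself (site L events go at the very end)
    focal_at: dict[int, list[int]] = {}
    for i, (site, _) in enumerate(focal_events):
        focal_at.setdefault(site, []).append(i)
    ref_at: dict[int, list[int]] = {}
    for i, (site, _) in enumerate(ref_events):
        ref_at.setdefault(site, []).append(i)

    col_kind: list[tuple[str, int, int]] = []  # (kind, event idx or site, offset)
    for site in range(L + 1):
        for i in focal_at.get(site, []):
            for off in range(focal_events[i][1].size):
                col_kind.append(("focal", i, off))
        for i in ref_at.get(site, []):
            for off in range(ref_events[i][1].size):
                col_kind.append(("ref", i, off))
        if site < L:
            col_kind.append(("anc", site, 0))
    n_cols = len(col_kind)

    anc_cols = np.array([k == "anc" for k, _, _ in col_kind])
    focal_cols = np.array([k == "focal" for k, _, _ in col_kind])
    ref_cols = np.array([k == "ref" for k, _, _ in col_kind])
    anc_src = np.array([i for k, i, _ in col_kind if k == "anc"], dtype=int)
    # events are site-sorted, so event columns appear in event-index order
    focal_flat_in_col_order = (
        np.concatenate([seq for _, seq in focal_events]) if focal_events else np.empty(0, int)
    )
    ref_flat_in_col_order = (
        np.concatenate([seq for _, seq in ref_events]) if ref_events else np.empty(0, int)
    )

    taxa = list(params.focal_taxa) + list(params.background_taxa)
    rows: list[str] = []
    gap_code = 20
    lut = np.array(list(AMINO_ACIDS + "-"))
    for taxon in taxa:
        row = np.full(n_cols, gap_code, dtype=int)
        mutated_anc = _mutate(anc, d_anc, rng)
        row[anc_cols] = mutated_anc[anc_src]
        if taxon in params.focal_taxa and focal_flat_in_col_order.size:
            row[focal_cols] = _mutate(
                focal_flat_in_col_order, params.subst_prob, rng
            )
        if taxon == params.reference and ref_flat_in_col_order.size:
            row[ref_cols] = ref_flat_in_col_order
        rows.append("".join(lut[row]))

    aln = Alignment(id=params.orthogroup, taxa=taxa, rows=rows)

    # true blocks with exact coordinates
    blocks: list[InsertionBlock] = []
    col_of_focal_event: dict[int, tuple[int, int]] = {}
    col_of_ref_event: dict[int, tuple[int, int]] = {}
    for j, (kind, i, off) in enumerate(col_kind):
        if kind == "focal":
            s, e = col_of_focal_event.get(i, (j, j))
            col_of_focal_event[i] = (min(s, j), j + 1)
        elif kind == "ref":
            s, e = col_of_ref_event.get(i, (j, j))
            col_of_ref_event[i] = (min(s, j), j + 1)

    # residue index = count of this taxon's residue columns before col_start
    focal_residue_col = anc_cols | focal_cols
    focal_cum = np.concatenate([[0], np.cumsum(focal_residue_col)])
    for i, (site, seq) in enumerate(focal_events):
        cs, ce = col_of_focal_event[i]
        for taxon in params.focal_taxa:
            rs = int(focal_cum[cs])
            blocks.append(
                InsertionBlock(
                    orthogroup=params.orthogroup,
                    taxon=taxon,
                    col_start=cs,
                    col_end=ce,
                    res_start=rs,
                    res_end=rs + seq.size,
                    length_res=int(seq.size),
                    cand_cols=int(seq.size),
                )
            )
    if params.reference is not None:
        ref_residue_col = anc_cols | ref_cols
        ref_cum = np.concatenate([[0], np.cumsum(ref_residue_col)])
        for i, (site, seq) in enumerate(ref_events):
            cs, ce = col_of_ref_event[i]
            rs = int(ref_cum[cs])
            blocks.append(
                InsertionBlock(
                    orthogroup=params.orthogroup,
                    taxon=params.reference,
                    col_start=cs,
                    col_end=ce,
                    res_start=rs,
                    res_end=rs + seq.size,
                    length_res=int(seq.size),
                    cand_cols=int(seq.size),
                )
            )
    blocks.sort(key=lambda b: (b.taxon, b.col_start))
    return aln, blocks


def expected_pooled_fraction(ins_rate: float, mean_len: float, other_rate: float = 0.0) -> float:
    """Analytic expectation of the pooled insertion fraction.

    With insertion load a = rate*mean_len on the quantified lineage and b
    on the other inserted lineage, the expected column share is
    a / (1 + a + b): inserted columns over ancestral-plus-inserted columns.
    """
    a = ins_rate * mean_len
    b = other_rate * mean_len
    return a / (1.0 + a + b)


def rates_for_pooled_fractions(
    f_focal: float, f_ref: float, mean_len: float
) -> tuple[float, float]:
    """Insertion rates that give target pooled focal/reference fractions.

    Inverts :func:`expected_pooled_fraction` for the two-lineage case.
    """
    if not (0 < f_focal < 1 and 0 <= f_ref < 1 and f_focal + f_ref < 1):
        raise InvalidParamsError("fractions must lie in (0,1) and sum below 1")
    denom = 1.0 - f_focal - f_ref
    a = f_focal / denom
    b = f_ref / denom
    return a / mean_len, b / mean_len


# ----------------------------------------------------------------------
# Phyletic table simulator
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class PhyleticSimParams:
    """Parameters of the phyletic-profile simulator.

    Genome sizes are log-normal: log10(size in Mb) ~ Normal(mu, sigma).
    The probability that a species lost all three C-NHEJ components is
    logistic in log10 size, expit(a + b*log10(size)); b < 0 concentrates
    losses in small genomes, b = 0 gives a size-independent null. The
    defaults emulate a census of ~230 eukaryotic genomes with roughly 9%
    triple-absent, concentrated in the smallest genomes.
    """

    n_species: int = 230
    mu: float = 2.2
    sigma: float = 0.9
    a: float = 4.25
    b: float = -3.0
    parasite_prob_bearing: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise InvalidParamsError("n_species must be >= 4")
        if self.sigma <= 0:
            raise InvalidParamsError("sigma must be > 0")
        if not (0 <= self.parasite_prob_bearing <= 1):
            raise InvalidParamsError("parasite_prob_bearing must be in [0, 1]")


_CLADES = ("Excavata", "Sar", "Archaeplastida", "Amoebozoa", "Opisthokonta")


def simulate_phyletic_table(
    params: PhyleticSimParams,
    rng: np.random.Generator | None = None,
) -> PhyleticProfile:
    """Simulate a species table with a controllable size-loss association.

    Species losing the pathway lose all three components together (the
    generator models complete pathway loss, not partial patterns); lost
    species are labelled parasites, retained species are parasites with a
    fixed background probability.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_species
    log10_size = rng.normal(params.mu, params.sigma, size=n)
    size_mb = np.power(10.0, log10_size)
    p_absent = 1.0 / (1.0 + np.exp(-(params.a + params.b * log10_size)))
    absent = rng.random(n) < p_absent
    parasite = absent | (rng.random(n) < params.parasite_prob_bearing)
    df = pd.DataFrame(
        {
            "species": [f"sp{i + 1:04d}" for i in range(n)],
            "clade": [_CLADES[i % len(_CLADES)] for i in range(n)],
            "lifestyle": np.where(parasite, "parasite", "free_living"),
            "genome_size_mb": size_mb,
            "ku70": (~absent).astype(int),
            "ku80": (~absent).astype(int),
            "lig4": (~absent).astype(int),
        }
    )
    return PhyleticProfile(df)


def synthetic_census_profile(
    counts: dict[int, int] | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> PhyleticProfile:
    """Synthetic stand-in for a published-style presence/absence table.

    Builds a profile whose component-count marginals are exactly
    ``counts`` (number of genomes encoding k of the three components,
    default the 181/26/3/20 split of a published census of 230
    eukaryotic genomes). Which components are retained in the
    partial classes, the genome sizes (smaller for pathway-lacking
    genomes) and the lifestyles are synthetic: only the marginal counts
    are faithful to the published census.
    """
    if counts is None:
        counts = {3: 181, 2: 26, 1: 3, 0: 20}
    if rng is None:
        rng = np.random.default_rng(seed)
    patterns = {
        3: [(1, 1, 1)],
        2: [(1, 1, 0), (1, 0, 1), (0, 1, 1)],
        1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
        0: [(0, 0, 0)],
    }
    rows = []
    i = 0
    for k in sorted(counts, reverse=True):
        for j in range(counts[k]):
            ku70, ku80, lig4 = patterns[k][j % len(patterns[k])]
            # pathway-lacking genomes drawn smaller, mirroring the
            # size contrast the census is used for
            mu = 1.4 if k == 0 else 2.4
            size = float(np.power(10.0, rng.normal(mu, 0.4)))
            rows.append(
                {
                    "species": f"sp{i + 1:04d}",
                    "clade": _CLADES[i % len(_CLADES)],
                    "lifestyle": "parasite" if k == 0 else "free_living",
                    "genome_size_mb": size,
                    "ku70": ku70,
                    "ku80": ku80,
                    "lig4": lig4,
                }
            )
            i += 1
    return PhyleticProfile(pd.DataFrame(rows))


def simulate_species_tree(
    labels: Sequence[str], rng: np.random.Generator | None = None, seed: int = 0
) -> SpeciesTree:
    """A random rooted binary topology over the given tip labels.

    Built by repeated random joins (a Yule-like shape); used to exercise
    the Dollo loss counter on profiles that carry no published tree.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    nodes = [str(l) for l in labels]
    if len(nodes) < 2:
        raise InvalidParamsError("need at least 2 tip labels")
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return read_newick(nodes[0] + ";")
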