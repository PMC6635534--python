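"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (string scans, exhaustive
enumeration) and share no code with the package internals, so they can
serve as independent checks of the optimized implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from kuscape.io_formats import AMINO_ACIDS, Alignment, PhyleticProfile

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def toy_alignment() -> Alignment:
    """One focal taxon with a 3-residue insertion against two backgrounds."""
    return Alignment(
        "og1",
        ["F", "B1", "B2"],
        ["MKAAPQRST", "MKA---RST", "MKA---RST"],
    )


@pytest.fixture
def small_profile() -> PhyleticProfile:
    df = pd.DataFrame(
        {
            "species": ["a", "b", "c", "d"],
            "clade": ["x"] * 4,
            "lifestyle": ["parasite", "parasite", "free_living", "free_living"],
            "genome_size_mb": [10.0, 20.0, 100.0, 200.0],
            "ku70": [0, 0, 1, 1],
            "ku80": [0, 0, 1, 1],
            "lig4": [0, 0, 1, 1],
        }
    )
    return PhyleticProfile(df)


# ----------------------------------------------------------------------
# Oracles
# ----------------------------------------------------------------------


def classify_columns_naive(
    rows_focal: list[str], rows_background: list[str], bg_gap_frac: float = 1.0
) -> list[bool]:
    """Per-column candidate scan written directly from the definition."""
    n = len(rows_focal[0])
    out = []
    for j in range(n):
        focal_res = any(r[j] != "-" for r in rows_focal)
        gap_frac = sum(r[j] == "-" for r in rows_background) / len(rows_background)
        out.append(focal_res and gap_frac >= bg_gap_frac)
    return out


def detect_blocks_naive(
    aln: Alignment,
    focal: list[str],
    background: list[str],
    bg_gap_frac: float = 1.0,
    merge_gap: int = 0,
    min_len: int = 3,
) -> list[tuple]:
    """Brute-force block caller: returns (taxon, col_start, col_end,
    res_start, res_end, length_res, cand_cols) tuples sorted like the
    package output."""
    cand = classify_columns_naive(
        [aln.row(t) for t in focal], [aln.row(t) for t in background], bg_gap_frac
    )
    runs = []
    j = 0
    n = len(cand)
    while j < n:
        if cand[j]:
            k = j
            while k < n and cand[k]:
                k += 1
            runs.append([j, k])
            j = k
        else:
            j += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    out = []
    for taxon in sorted(focal):
        row = aln.row(taxon)
        for s, e in merged:
            length_res = sum(1 for j in range(s, e) if cand[j] and row[j] != "-")
            if length_res < min_len:
                continue
            res_start = sum(1 for c in row[:s] if c != "-")
            res_end = res_start + sum(1 for c in row[s:e] if c != "-")
            cand_cols = sum(cand[s:e])
            out.append((taxon, s, e, res_start, res_end, length_res, cand_cols))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def dollo_bruteforce(tree, tip_states: dict[str, int]) -> int:
    """Exhaustive minimum losses under single-origin Dollo parsimony.

    Internal nodes (and the root) take any 0/1 state such that no edge
    gains the character (0 -> 1 forbidden); a root state of 0 counts as
    one loss on the root's subtending edge. Unscored tips are free.
    """
    nodes = list(tree.tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    root = tree.root
    best = None
    for assign in itertools.product([0, 1], repeat=len(internal)):
        st = {id(n): s for n, s in zip(internal, assign)}
        losses = 1 - st[id(root)]  # loss on the root edge if root is 0
        ok = True
        for n in nodes:
            if n is root:
                continue
            ps = st[id(n.parent_node)]
            if n.is_leaf():
                label = n.taxon.label
                if label not in tip_states:
                    continue  # pruned tip: unconstrained
                cs = tip_states[label]
            else:
                cs = st[id(n)]
            if ps == 0 and cs == 1:
                ok = False
                break
            if ps == 1 and cs == 0:
                losses += 1
        if ok and (best is None or losses < best):
            best = losses
    return best


def mannwhitney_exact_enum(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of all group splits."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(idx: tuple[int, ...]) -> float:
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum(
            1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys
        )

    mid = n1 * (len(pooled) - n1) / 2
    obs = abs(u_stat(tuple(range(n1))) - mid)
    splits = list(itertools.combinations(range(len(pooled)), n1))
    extreme = sum(1 for idx in splits if abs(u_stat(idx) - mid) >= obs - 1e-12)
    return extreme / len(splits)


def wilcoxon_exact_enum(diffs) -> float:
    """Two-sided exact Wilcoxon signed-rank p by sign-vector enumeration."""
    d = [v for v in diffs if v != 0]
    n = len(d)
    if n == 0:
        return 1.0
    order = sorted(range(n), key=lambda i: abs(d[i]))
    ranks = [0.0] * n
    # midranks for tied absolute values
    i = 0
    while i < n:
        j = i
        while j < n and abs(d[order[j]]) == abs(d[order[i]]):
            j += 1
        mid = (i + j + 1) / 2
        for k in range(i, j):
            ranks[order[k]] = mid
        i = j
    mid_t = n * (n + 1) / 4

    def t_plus(signs) -> float:
        return sum(r for r, s in zip(ranks, signs) if s > 0)

    obs = abs(t_plus([1 if v > 0 else -1 for v in d]) - mid_t)
    total = 0
    extreme = 0
    for signs in itertools.product([1, -1], repeat=n):
        total += 1
        if abs(t_plus(signs) - mid_t) >= obs - 1e-12:
            extreme += 1
    return extreme / total


def random_gapped_alignment(
    rng: np.random.Generator, n_taxa: int, n_cols: int, gap_prob: float = 0.3
) -> Alignment:
    """Random alignment for property tests (no all-gap rows enforced)."""
    letters = np.array(list(AMINO_ACIDS))
    rows = []
    for i in range(n_taxa):
        chars = letters[rng.integers(0, 20, size=n_cols)]
        gaps = rng.random(n_cols) < gap_prob
        row = np.where(gaps, "-", chars)
        rows.append("".join(row))
    return Alignment("ogR", [f"t{i}" for i in range(n_taxa)], rows)
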