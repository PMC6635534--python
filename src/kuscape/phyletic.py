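"""Phyletic-profile analyses of the classical-NHEJ machinery.

Three operations reproduce the comparative-genomics side of the study of
C-NHEJ loss in eukaryotes:

* :func:`component_census` — how many genomes retain 3, 2, 1 or 0 of the
  core components (Ku70, Ku80, Lig4);
* :func:`size_contrast` — genome-size comparison between genomes lacking
  all three components and genomes retaining at least one;
* :func:`dollo_min_losses` — minimum number of independent losses of a
  component on a rooted species tree under Dollo parsimony (single origin,
  ancestral presence, no regain).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateGroupError,
    EmptyProfileError,
    UnknownTipError,
)
from .io_formats import COMPONENTS, PhyleticProfile, SpeciesTree

__all__ = [
    "ComponentCensus",
    "SizeContrast",
    "DolloResult",
    "component_census",
    "size_contrast",
    "dollo_min_losses",
]


# ----------------------------------------------------------------------
# Component census
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentCensus:
    """Number of genomes encoding k of the three core components.

    ``counts[k]`` is the number of genomes with exactly ``k`` components
    present among Ku70, Ku80 and Lig4; rows with any missing (NA) call are
    tallied in ``excluded`` rather than being coerced to absence.
    """

    counts: dict[int, int]
    excluded: int

    @property
    def n_scored(self) -> int:
        return sum(self.counts.values())


def component_census(
    profile: PhyleticProfile, exclude: set[str] | None = None
) -> ComponentCensus:
    """Count genomes by how many C-NHEJ components they encode.

    Parameters
    ----------
    profile
        Phyletic profile with 0/1/NA calls for ku70, ku80, lig4.
    exclude
        Optional species ids to drop before counting (e.g. genomes with
        engineered deletions of the pathway).
    """
    df = profile.df
    if exclude:
        df = df[~df["species"].isin(exclude)]
    if df.empty:
        raise EmptyProfileError("profile has no rows to census")
    calls = df[list(COMPONENTS)]
    has_na = calls.isna().any(axis=1)
    excluded = int(has_na.sum())
    if excluded:
        warnings.warn(
            f"{excluded} genome(s) with NA component calls excluded from census",
            stacklevel=2,
        )
    k = calls[~has_na].sum(axis=1).astype(int)
    counts = {int(key): int(val) for key, val in k.value_counts().items()}
    return ComponentCensus(counts=counts, excluded=excluded)


# ----------------------------------------------------------------------
# Genome-size contrast
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class SizeContrast:
    """Genome-size comparison between C-NHEJ-lacking and -bearing genomes.

    "Lacking" means all three of Ku70, Ku80 and Lig4 absent; "bearing"
    means at least one present. ``p_value``/``test_name`` describe the
    primary test (Mann-Whitney U on raw Mb sizes, two-sided); a Welch
    t-test on log10 sizes is reported alongside because genome sizes are
    heavy-tailed.
    """

    n_lacking: int
    n_bearing: int
    mean_lacking_mb: float
    mean_bearing_mb: float
    median_lacking_mb: float
    median_bearing_mb: float
    ratio: float
    p_value: float
    test_name: str
    statistic: float
    p_value_welch_log10: float | None
    excluded: int = 0


#: Combined sample size up to which the Mann-Whitney p-value is exact
#: (only without ties; ties force the tie-corrected normal approximation).
MWU_EXACT_MAX_N = 20


def _mannwhitney_two_sided(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U; exact for small untied samples."""
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if pooled.std() == 0:
        # all observations identical: no evidence either way
        return float(len(x) * len(y) / 2), 1.0, "mannwhitneyu_degenerate"
    if len(pooled) <= MWU_EXACT_MAX_N and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "mannwhitneyu_exact"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "mannwhitneyu_normal_tie_corrected"


def size_contrast(
    profile: PhyleticProfile, exclude: set[str] | None = None
) -> SizeContrast:
    """Contrast genome sizes of C-NHEJ-lacking vs -bearing genomes.

    Rows with any NA component call or missing genome size are excluded
    (with a warning) because group membership cannot be established.
    """
    df = profile.df
    if exclude:
        df = df[~df["species"].isin(exclude)]
    calls = df[list(COMPONENTS)]
    usable = ~calls.isna().any(axis=1) & df["genome_size_mb"].notna()
    n_excluded = int((~usable).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} genome(s) with NA calls or missing size excluded "
            "from the size contrast",
            stacklevel=2,
        )
    df = df[usable]
    present_any = df[list(COMPONENTS)].sum(axis=1).astype(int) > 0
    lacking = df.loc[~present_any, "genome_size_mb"].to_numpy(float)
    bearing = df.loc[present_any, "genome_size_mb"].to_numpy(float)
    if len(lacking) == 0 or len(bearing) == 0:
        raise DegenerateGroupError(
            f"empty group: n_lacking={len(lacking)}, n_bearing={len(bearing)}"
        )
    stat, p, test_name = _mannwhitney_two_sided(lacking, bearing)
    # secondary test on log10 sizes (sizes are > 0 by profile invariant)
    if len(lacking) >= 2 and len(bearing) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            welch = sps.ttest_ind(
                np.log10(bearing), np.log10(lacking), equal_var=False
            )
        p_welch = None if math.isnan(welch.pvalue) else float(welch.pvalue)
    else:
        p_welch = None
    return SizeContrast(
        n_lacking=len(lacking),
        n_bearing=len(bearing),
        mean_lacking_mb=float(lacking.mean()),
        mean_bearing_mb=float(bearing.mean()),
        median_lacking_mb=float(np.median(lacking)),
        median_bearing_mb=float(np.median(bearing)),
        ratio=float(bearing.mean() / lacking.mean()),
        p_value=p,
        test_name=test_name,
        statistic=stat,
        p_value_welch_log10=p_welch,
        excluded=n_excluded,
    )


# ----------------------------------------------------------------------
# Dollo minimum losses
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class DolloResult:
    """Minimum independent losses of one component on a species tree.

    ``loss_edges`` identifies each loss by the child node of the edge on
    which it occurs: the tip label for terminal edges, a canonical
    ``mrca(tip,...)`` label for internal edges, and ``root`` when every
    scored tip lacks the component (a single loss on the root edge).
    """

    component: str
    min_losses: int
    loss_edges: tuple[str, ...]
    n_scored_tips: int
    n_pruned_tips: int


def _node_edge_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    tips = sorted(
        leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon is not None
    )
    return "mrca(" + ",".join(tips) + ")"


def dollo_min_losses(
    tree: SpeciesTree,
    tip_states: dict[str, int],
    component: str = "component",
) -> DolloResult:
    """Minimum number of independent losses under Dollo parsimony.

    The character is assumed present at the root (single ancient origin);
    regain is forbidden, so the parsimony minimum equals the number of
    maximal subtrees whose scored tips are all absent, and each loss maps
    onto the edge subtending such a subtree. Tips on the tree without a
    state are pruned from the computation with a warning; a state for a
    label not on the tree is an error.
    """
    labels = set(tree.tip_labels)
    unknown = set(tip_states) - labels
    if unknown:
        raise UnknownTipError(f"state(s) given for unknown tip(s) {sorted(unknown)}")
    for state in tip_states.values():
        if state not in (0, 1):
            raise ValueError(f"tip states must be 0/1, got {state!r}")
    pruned = labels - set(tip_states)
    if pruned:
        warnings.warn(
            f"{len(pruned)} tip(s) without a state pruned from Dollo scoring",
            stacklevel=2,
        )
    if not tip_states:
        raise UnknownTipError("no scored tips on the tree")

    # post-order: does each subtree contain scored tips, and are they all absent?
    n_scored: dict[int, int] = {}
    all_absent: dict[int, bool] = {}
    for node in tree.tree.postorder_node_iter():
        nid = id(node)
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label in tip_states:
                n_scored[nid] = 1
                all_absent[nid] = tip_states[label] == 0
            else:
                n_scored[nid] = 0
                all_absent[nid] = True  # vacuous
        else:
            kids = [id(c) for c in node.child_nodes()]
            n_scored[nid] = sum(n_scored[k] for k in kids)
            all_absent[nid] = all(all_absent[k] for k in kids)

    root = tree.root
    if all_absent[id(root)]:
        return DolloResult(
            component=component,
            min_losses=1,
            loss_edges=("root",),
            n_scored_tips=len(tip_states),
            n_pruned_tips=len(pruned),
        )

    loss_edges: list[str] = []
    for node in tree.tree.preorder_node_iter():
        nid = id(node)
        if n_scored[nid] == 0:
            continue
        parent = node.parent_node
        if all_absent[nid] and (parent is None or not all_absent[id(parent)]):
            loss_edges.append(_node_edge_label(node))
    loss_edges.sort()
    return DolloResult(
        component=component,
        min_losses=len(loss_edges),
        loss_edges=tuple(loss_edges),
        n_scored_tips=len(tip_states),
        n_pruned_tips=len(pruned),
    )
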