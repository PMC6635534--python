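"""Composition enrichment, paired tests, flank divergence, conservation."""

import itertools
import math

import numpy as np
import pytest

from conftest import mannwhitney_exact_enum, wilcoxon_exact_enum
from kuscape.errors import (
    ConstantInputError,
    EmptyPoolError,
    InsufficientOverlapError,
    NoDistalColumnsError,
    TooFewAlignmentsError,
    TooFewPairsError,
)
from kuscape.io_formats import AMINO_ACIDS, Alignment
from kuscape.insertions import DetectionParams, FocalPartition, detect_insertion_blocks
from kuscape.phyletic import _mannwhitney_two_sided
from kuscape.stats import (
    CompositionTable,
    compare_fraction_paired,
    composition_enrichment,
    conservation_vs_insertion,
    enrichment_similarity,
    flank_divergence,
    g_test_2x2,
)
from kuscape.synthetic import OrthogroupSimParams, simulate_orthogroup


def composition_fixture():
    """Alignment whose focal insertion is 8 A + 2 G over a 50 A + 50 G rest."""
    body = "A" * 50 + "G" * 50
    aln = Alignment("og1", ["F", "B"], [body + "A" * 8 + "G" * 2, body + "-" * 10])
    blocks = detect_insertion_blocks(aln, FocalPartition(["F"], ["B"]))
    return aln, blocks


class TestCompositionEnrichment:
    def test_enrichment_ratios(self):
        aln, blocks = composition_fixture()
        table = composition_enrichment([aln], blocks, "F")
        assert table.enrichment["A"] == pytest.approx(1.6)
        assert table.enrichment["G"] == pytest.approx(0.4)
        assert table.counts_insertion["A"] == 8
        assert math.isnan(table.enrichment["C"])  # absent from background

    def test_identical_composition_unit_enrichment(self):
        body = ("AG" * 25) * 2
        aln = Alignment("og1", ["F", "B"], [body + "AGAG", body + "----"])
        blocks = detect_insertion_blocks(aln, FocalPartition(["F"], ["B"]))
        table = composition_enrichment([aln], blocks, "F")
        assert table.enrichment["A"] == pytest.approx(1.0)
        assert table.enrichment["G"] == pytest.approx(1.0)
        assert table.omnibus_g == pytest.approx(0.0, abs=1e-9)

    def test_empty_pool(self):
        aln = Alignment("og1", ["F", "B"], ["AAAA", "AAAA"])
        with pytest.raises(EmptyPoolError):
            composition_enrichment([aln], [], "F")

    def test_x_excluded(self):
        body = "A" * 20
        aln = Alignment("og1", ["F", "B"], [body + "AXA", body + "---"])
        blocks = detect_insertion_blocks(aln, FocalPartition(["F"], ["B"]))
        table = composition_enrichment([aln], blocks, "F")
        assert table.n_insertion == 2  # X not counted

    def test_bh_qvalues_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        letters = np.array(list(AMINO_ACIDS))
        ins = "".join(rng.choice(letters, size=200))
        bg = "".join(rng.choice(letters, size=2000))
        aln = Alignment("og1", ["F", "B"], [bg + ins, bg + "-" * len(ins)])
        blocks = detect_insertion_blocks(aln, FocalPartition(["F"], ["B"]))
        table = composition_enrichment([aln], blocks, "F")
        defined = [aa for aa in AMINO_ACIDS if not math.isnan(table.p_values[aa])]
        pairs = sorted((table.p_values[aa], table.q_values[aa]) for aa in defined)
        qs = [q for _, q in pairs]
        assert all(q <= 1 for q in qs)
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(q >= p for (p, q) in pairs)  # BH never shrinks a p-value


class TestGTest:
    def test_zero_iff_identical_composition(self):
        g, p = g_test_2x2([[10, 10], [20, 20]])
        assert g == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_nonnegative_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            tbl = rng.integers(0, 30, size=(2, 2))
            g, p = g_test_2x2(tbl)
            assert g >= 0
            if not math.isnan(p):
                assert 0 <= p <= 1

    def test_degenerate_margin_undefined(self):
        g, p = g_test_2x2([[0, 10], [0, 20]])
        assert math.isnan(p)


class TestEnrichmentSimilarity:
    @staticmethod
    def table_from_enrichment(taxon, enr):
        full = {aa: float("nan") for aa in AMINO_ACIDS}
        full.update(enr)
        zeros = {aa: 0 for aa in AMINO_ACIDS}
        return CompositionTable(
            taxon=taxon, counts_insertion=zeros, counts_background=zeros,
            enrichment=full, p_values=dict(full), q_values=dict(full),
            omnibus_g=0.0, omnibus_p=1.0,
        )

    def test_identical_tables_correlation_one(self):
        enr = {"A": 1.5, "G": 0.5, "P": 2.0, "K": 0.8, "S": 1.2}
        t1 = self.table_from_enrichment("x", enr)
        t2 = self.table_from_enrichment("y", enr)
        sim = enrichment_similarity([t1, t2])
        assert sim.loc["x", "y"] == pytest.approx(1.0)

    def test_antithetic_vectors(self):
        t1 = self.table_from_enrichment("x", {"A": 2.0, "G": 1.0, "P": 0.5})
        t2 = self.table_from_enrichment("y", {"A": 0.5, "G": 1.0, "P": 2.0})
        sim = enrichment_similarity([t1, t2], min_shared=3)
        assert sim.loc["x", "y"] == pytest.approx(-1.0)

    def test_insufficient_overlap(self):
        t1 = self.table_from_enrichment("x", {"A": 2.0})
        t2 = self.table_from_enrichment("y", {"A": 0.5})
        with pytest.raises(InsufficientOverlapError):
            enrichment_similarity([t1, t2])

    def test_shared_insertion_composition_gives_high_similarity(self):
        """Two focal taxa sharing an insertion-composition vector yield
        strongly correlated enrichment patterns (simulation property)."""
        rng = np.random.default_rng(31)
        corrs = []
        for _ in range(100):
            alignments, blocks = [], []
            for i in range(12):
                params = OrthogroupSimParams(
                    length=200,
                    focal_taxa=("jacA", "jacB"),
                    background_taxa=("T1", "T2"),
                    reference=None,
                    subst_prob=0.02,
                    ins_rate=0.015,
                    ins_mean_len=6.0,
                    orthogroup=f"OG{i}",
                )
                aln, true = simulate_orthogroup(params, rng=rng)
                alignments.append(aln)
                blocks.extend(true)
            tables = [
                composition_enrichment(alignments, blocks, t)
                for t in ("jacA", "jacB")
            ]
            sim = enrichment_similarity(tables, min_shared=5)
            corrs.append(sim.iloc[0, 1])
        assert np.mean(corrs) > 0.8


class TestComparePaired:
    def test_identical_vectors(self):
        f = {"a": 0.1, "b": 0.2, "c": 0.3}
        res = compare_fraction_paired(f, dict(f))
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_exact_small_example(self):
        res = compare_fraction_paired(
            {"a": 0.2, "b": 0.3, "c": 0.25}, {"a": 0.1, "b": 0.1, "c": 0.1}
        )
        assert res.p_value == pytest.approx(0.25)
        assert res.test_name == "wilcoxon_exact"

    def test_antisymmetry(self):
        f = {"a": 0.2, "b": 0.3, "c": 0.25, "d": 0.15}
        r = {"a": 0.1, "b": 0.35, "c": 0.1, "d": 0.1}
        fwd = compare_fraction_paired(f, r)
        rev = compare_fraction_paired(r, f)
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert fwd.statistic == pytest.approx(-rev.statistic)

    def test_too_few_pairs(self):
        with pytest.raises(TooFewPairsError):
            compare_fraction_paired({"a": 0.1, "b": 0.2}, {"a": 0.2, "b": 0.1})

    def test_pairs_matched_by_orthogroup(self):
        f = {"a": 0.2, "b": 0.3, "c": 0.25, "zzz": 0.9}
        r = {"a": 0.1, "b": 0.1, "c": 0.1, "yyy": 0.0}
        res = compare_fraction_paired(f, r)
        assert res.n_alignments == 3

    @pytest.mark.parametrize("n", range(1, 9))
    def test_exact_p_matches_sign_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(8):
            mags = rng.permutation(np.arange(1, n + 1)) * 0.013
            signs = rng.choice([-1.0, 1.0], size=n)
            d = mags * signs
            focal = {f"og{i}": 0.5 + v for i, v in enumerate(d)}
            ref = {f"og{i}": 0.5 for i in range(n)}
            res = compare_fraction_paired(focal, ref, min_pairs=1)
            assert res.p_value == pytest.approx(wilcoxon_exact_enum(d), abs=1e-10)

    def test_null_rejection_rate_calibrated(self):
        """Equal insertion rates in focal and reference lineages: the
        paired test rejects at ~alpha (size calibration, 2000 replicates)."""
        rng = np.random.default_rng(99)
        n_rep, n_aln = 2000, 20
        rate = 0.05
        rejections = 0
        for _ in range(n_rep):
            focal_fracs, ref_fracs = {}, {}
            for i in range(n_aln):
                params = OrthogroupSimParams(
                    length=60,
                    focal_taxa=("F",),
                    background_taxa=("R",),
                    reference="R",
                    subst_prob=0.0,
                    ins_rate=rate,
                    ref_ins_rate=rate,
                    ins_mean_len=3.0,
                    orthogroup=f"OG{i}",
                )
                aln, true = simulate_orthogroup(params, rng=rng)
                n_cols = aln.n_cols
                focal_fracs[aln.id] = (
                    sum(b.cand_cols for b in true if b.taxon == "F") / n_cols
                )
                ref_fracs[aln.id] = (
                    sum(b.cand_cols for b in true if b.taxon == "R") / n_cols
                )
            res = compare_fraction_paired(focal_fracs, ref_fracs)
            rejections += res.p_value <= 0.05
        rate_hat = rejections / n_rep
        assert 0.03 <= rate_hat <= 0.07


class TestMannWhitneyExact:
    @pytest.mark.parametrize(
        "n1,n2", [(n1, n2) for n1 in range(1, 5) for n2 in range(n1, 9 - n1)]
    )
    def test_matches_enumeration_all_small_sizes(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(10):
            vals = rng.permutation(np.arange(1, n1 + n2 + 1) * 1.7)
            x, y = vals[:n1], vals[n1:]
            stat, p, name = _mannwhitney_two_sided(x, y)
            assert name == "mannwhitneyu_exact"
            assert p == pytest.approx(mannwhitney_exact_enum(x, y), abs=1e-10)


class TestFlankDivergence:
    def flank_case(self):
        #       d  d  f      B  f  d
        rows_f = "A  A  K  W  A  A".split()
        aln = Alignment(
            "og",
            ["F", "B1", "B2"],
            ["AAKWAA", "AAK-AA", "AAR-AA"],
        )
        part = FocalPartition(["F"], ["B1", "B2"])
        blocks = detect_insertion_blocks(aln, part, DetectionParams(min_len=1))
        return aln, blocks, part

    def test_hand_counted_rates(self):
        aln, blocks, part = self.flank_case()
        fd = flank_divergence(aln, blocks, flank_width=1, partition=part)
        assert fd.flank_mismatch_rate == pytest.approx(0.25)
        assert fd.distal_mismatch_rate == 0.0
        assert math.isinf(fd.ratio)

    def test_identical_outside_blocks_ratio_one(self):
        aln = Alignment("og", ["F", "B"], ["AAKWAA", "AAK-AA"])
        part = FocalPartition(["F"], ["B"])
        blocks = detect_insertion_blocks(aln, part, DetectionParams(min_len=1))
        fd = flank_divergence(aln, blocks, flank_width=1, partition=part)
        assert fd.flank_mismatch_rate == 0.0 and fd.ratio == 1.0

    def test_no_distal_columns(self):
        aln = Alignment("og", ["F", "B"], ["AKA", "A-A"])
        part = FocalPartition(["F"], ["B"])
        blocks = detect_insertion_blocks(aln, part, DetectionParams(min_len=1))
        with pytest.raises(NoDistalColumnsError):
            flank_divergence(aln, blocks, flank_width=5, partition=part)

    def test_elevated_flank_substitution_detected(self):
        """3x flank substitution in the generator gives median ratio > 2
        over replicates (simulation property)."""
        rng = np.random.default_rng(17)
        ratios = []
        for i in range(200):
            params = OrthogroupSimParams(
                length=300,
                focal_taxa=("jacA", "jacB"),
                background_taxa=("T1", "T2"),
                reference=None,
                subst_prob=0.05,
                ins_rate=0.01,
                ins_mean_len=6.0,
                flank_mult=3.0,
                flank_width=5,
                orthogroup=f"OG{i}",
            )
            aln, true = simulate_orthogroup(params, rng=rng)
            if not true:
                continue
            part = FocalPartition(params.focal_taxa, params.background_taxa)
            try:
                fd = flank_divergence(aln, true, flank_width=5, partition=part)
            except (NoDistalColumnsError, Exception):
                continue
            if math.isfinite(fd.ratio):
                ratios.append(fd.ratio)
        assert len(ratios) >= 150
        assert np.median(ratios) > 2


class TestConservationVsInsertion:
    def test_perfect_antitone(self):
        rho, p = conservation_vs_insertion(
            [(0.9, 0.00), (0.8, 0.05), (0.5, 0.10), (0.4, 0.20)]
        )
        assert rho == pytest.approx(-1.0)

    def test_constant_fraction(self):
        with pytest.raises(ConstantInputError):
            conservation_vs_insertion([(0.9, 0.1), (0.8, 0.1), (0.5, 0.1), (0.4, 0.1)])

    def test_too_few(self):
        with pytest.raises(TooFewAlignmentsError):
            conservation_vs_insertion([(0.9, 0.1), (0.8, 0.2), (0.5, 0.3)])

    def test_order_invariance(self):
        recs = [(0.9, 0.02), (0.8, 0.07), (0.5, 0.04), (0.4, 0.20), (0.3, 0.11)]
        rho1, _ = conservation_vs_insertion(recs)
        rho2, _ = conservation_vs_insertion(list(reversed(recs)))
        assert rho1 == pytest.approx(rho2)
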