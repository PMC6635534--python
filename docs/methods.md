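# Methods

`kuscape` implements two linked comparative-genomics analyses around the
classical nonhomologous end-joining (C-NHEJ) pathway in eukaryotes: (i)
phyletic profiling of the three widely conserved core components — Ku70,
Ku80 and DNA ligase IV (Lig4) — across a set of genomes, with a
genome-size contrast and a minimum-loss count on a species tree; and
(ii) detection and quantification of lineage-specific insertions in
orthologous protein alignments, the signature left in trypanosomatid
proteomes after loss of the Ku heterodimer. This note records the models,
the parameters that matter, the numerical conventions, and what the
synthetic data do and do not establish.

## Phyletic profiling

**Data model.** A profile row is (species, clade, lifestyle, genome size
in Mb, ku70, ku80, lig4) with component calls in {0, 1, NA}. NA means
"no call could be made in the source database" and is never coerced to
absence: census and contrast operations exclude NA-bearing rows and warn.
This matters because absence of evidence in an orthology database is not
evidence of pathway loss.

**Component census** partitions genomes by k = number of components
present (0–3). An explicit exclusion list supports removing genomes with
engineered pathway deletions from the census rather than hard-coding
them.

**Genome-size contrast.** "Lacking C-NHEJ" is the strict reading: all
three components absent; "bearing" is at least one present, so a genome
retaining only Ku (the trypanosomatid configuration) counts as bearing.
The primary test is a two-sided Mann–Whitney U on raw Mb sizes — exact
when the combined sample is ≤ 20 without ties, otherwise the
tie-corrected normal approximation; a fully tied input returns p = 1.
Genome sizes are heavy-tailed (they span nucleomorphs to plants), so a
Welch t-test on log10 sizes is computed alongside and both are reported.
No claim is made that either test reproduces any particular published
p-value, since the original test is unnamed.

**Dollo loss counting.** The pathway is assumed anciently present
(single origin; it is conserved from bacteria onward), and regain is
forbidden. Under this model the parsimony minimum for a 0/1 tip
character equals the number of maximal subtrees whose scored tips are
all absent, and each loss maps to the edge subtending one such subtree.
Conventions: tips without a state are pruned with a warning; a state for
a label not on the tree is an error; if every scored tip is absent the
count is one loss on the root's subtending edge; under a polytomy each
absent child subtree whose sibling set contains a present tip counts as
one loss, which makes the edge assignment deterministic. The
implementation is validated against exhaustive enumeration of internal
state assignments (all rooted binary topologies to 5 tips × all state
vectors, plus random multifurcating 6–8-tip trees × all state vectors).
No probabilistic ancestral-state reconstruction is attempted, and loss
counts are reported without correction for phylogenetic
non-independence.

## Insertion detection

**Definition.** Given an alignment and a partition of its taxa into a
focal set and a background set, a column is an *insertion candidate* iff
at least one focal taxon has a residue there and the fraction of
background taxa gapped there is ≥ `bg_gap_frac` (default 1.0 — every
background taxon gapped). Maximal candidate runs become blocks; runs
separated by ≤ `merge_gap` non-candidate columns (default 0) are merged;
per focal taxon a block is emitted only if that taxon has ≥ `min_len`
residues in the run's candidate columns (default 3, suppressing
single-residue alignment noise). Coordinates are 0-based half-open in
memory for both columns and ungapped residues, 1-based inclusive on
disk.

One subtlety: with a nonzero merge gap a block may span interior
non-candidate columns, so the residue interval of the full span can
exceed `length_res` (which counts candidate-column residues only);
equality holds at the default `merge_gap = 0`. The numerator of every
insertion fraction is candidate columns only; the denominator is the
full alignment width. Both pooled (Σ numerators / Σ denominators) and
per-alignment-mean aggregations are reported, since a published share
"of the alignments" admits either reading.

**Per-species quantification is symmetric.** To quantify one species,
that species alone is focal and *everything* else — including its close
relatives — is background. To quantify insertions shared by a clade
(e.g. both "jaculum" species), the whole clade is focal. This is how a
reference taxon such as *T. brucei* gets its own fraction on the same
footing as the focal clade.

**Truncated sequences.** A background model missing its N- or C-terminus
would masquerade as a focal insertion. The optional
`ignore_terminal_gaps` flag treats a background taxon's terminal gap
runs as missing data (removed from both numerator and denominator of
the gap fraction). Off by default because it also hides true terminal
extensions.

**Peptide coverage.** A peptide covers an insertion interval iff some
exact occurrence overlaps it by ≥ 1 residue; all (overlapping)
occurrences are searched, and I/L can be treated as equivalent (they are
isobaric in mass spectrometry). This implements the check that
insertions are retained in mature proteins.

## Statistics

* **Composition enrichment.** For one taxon, amino acids are counted in
  its block columns vs everywhere else in its own rows ('X' excluded
  from both pools). Enrichment is the ratio of relative frequencies;
  undefined (NaN sentinel, serialized as `"undefined"`) when the residue
  never occurs in the background pool. Per-residue significance uses a
  2×2 G-test (this residue vs the other 19 × insertion vs background)
  with Benjamini–Hochberg q-values at the conventional FDR scale, plus
  an omnibus 2×20 G-test. The G statistic is computed with 0·log 0 = 0,
  so sparse rows are handled without continuity hacks; a zero margin
  makes the test undefined rather than significant.
* **Enrichment similarity** between taxa is the Pearson correlation of
  log2 enrichment over amino acids with finite positive enrichment in
  both tables; fewer than 5 shared residues (configurable) is an error,
  not a quietly unstable number.
* **Paired fraction comparison** is a two-sided Wilcoxon signed-rank
  test on per-orthogroup fraction differences, zeros dropped; exact for
  ≤ 25 untied nonzero differences, otherwise normal approximation with
  continuity and tie correction. Chosen because fractions are paired by
  orthogroup and far from normal.
* **Flank divergence** compares focal-vs-background residue mismatch
  rates in fully gap-free columns within `flank_width` columns (default
  5; no published width exists) of any block boundary against all other
  gap-free non-block columns. Both rates zero → ratio 1; mismatches only
  in flanks → ratio +inf, serialized as the explicit sentinel `"+inf"`.
* **Conservation vs insertion load**: conservation is mean pairwise
  identity over non-candidate gap-free columns; the association with
  per-alignment insertion fraction is Spearman's rho (two-sided).
  Constant inputs are an error, not rho = 0.

All exact nonparametric p-values are verified against full-enumeration
oracles for every rank configuration with n ≤ 8.

## Synthetic data generator

`simulate_orthogroup` emits the *true* alignment directly from known
homology — no aligner runs — so detection performance is measured
without aligner error (aligner robustness is explicitly out of scope).
The model:

* ancestral sequence of length L, uniform over the 20 amino acids;
* per-terminal-branch substitutions, i.i.d. per site with probability
  `subst_prob` (default 0.05), replacement uniform over the 19
  alternatives — no exchangeability matrix, which is deliberate: the
  detector only sees gap structure, and the statistics layer only needs
  a controllable mismatch rate;
* focal-lineage insertion events at Poisson(`ins_rate`·L) distinct
  sites, geometric lengths with mean `ins_mean_len` (default 8, support
  ≥ 1), residues drawn from a 20-simplex that defaults to a mildly
  low-complexity-skewed vector (young insertions are rarely average
  protein); events are shared by the whole focal clade, then diverge by
  terminal-branch substitution;
* optional reference-private insertions at `ref_ins_rate` on one
  background taxon, so focal-vs-reference regimes can be posed;
* a flank multiplier (`flank_mult`, default 1 = off) that raises the
  substitution probability for all taxa within `flank_width` ancestral
  sites of an insertion point, emulating the elevated divergence
  observed around indels.

The pooled insertion fraction has the closed form a/(1 + a + b) with
a = rate·mean length on the quantified lineage and b the other
lineage's load; `rates_for_pooled_fractions` inverts it, and parameter
recovery is checked at L = 2,000 within 10% relative error.
Everything is driven by one `numpy` Generator; a fixed seed reproduces
outputs byte for byte. Deletions, nucleotide-level events and
per-focal-species private insertion rates are not modeled in this
version — the last is why both focal species pool at the same expected
fraction rather than at two distinct values.

`simulate_phyletic_table` draws log10 genome size from Normal(μ, σ)
(defaults μ = 2.2, σ = 0.9 on Mb — medians ~160 Mb with a heavy spread,
a plausible eukaryote panel) and sets the species to triple-absent with
logistic probability expit(a + b·log10 size). Defaults a = 4.25,
b = −3.0 give roughly 9% lacking species concentrated in the smallest
genomes, echoing a ~230-genome census with 20 triple-absent genomes;
b = 0 is the null for type-I calibration. Loss is all-or-none (no
partial component patterns), lost species are labelled parasites, and
retained species are parasites with probability 0.25. A companion
random-join tree generator supplies rooted topologies for Dollo runs;
it has no branch lengths and no phylogenetic signal in the loss
pattern, so simulated Dollo counts are close to the number of lacking
species — real data, with clustered losses, give far fewer.

`synthetic_census_profile` is a stand-in, not a simulation: its
component-count marginals are fixed exactly (default 181/26/3/20 over
230 genomes) while sizes, clades and which components are retained in
partial classes are synthetic.

**What passing tests show, and don't.** The generator reproduces the
*statistical structure* each stage assumes (gap-defined insertions,
paired fractions, composition shifts, flank divergence), so green tests
establish correctness of detection and inference under that structure.
They do not establish robustness to real-world aligner error, assembly
truncation (partially mitigated by `ignore_terminal_gaps`), paralog
contamination, or non-uniform substitution processes.

## Problem sizes used in checks

Scales chosen for the standard verification runs: 247 alignments of
ancestral length 1,000 (the study-scale insertion regime, calibrated to
pooled fractions 0.15 focal / 0.09 reference); 2,000 replicates for
type-I calibration of the size-contrast tests (230 species, null slope)
and of the paired Wilcoxon (20 alignments of length 60 per replicate);
200 replicates at L = 2,000 for parameter recovery; 25 replicates of
the full 247-alignment regime for power. In regime quantification runs
detection uses `min_len = 1`, because simulated alignments carry none of
the aligner noise the default length filter exists to suppress, and the
filter would otherwise truncate genuine short insertions (geometric
lengths put ~23% of events below 3 residues).

## Known limitations

* Dollo counts assume the tree is correct and treat each component
  independently; no statistical dependence between Ku70/Ku80/Lig4 losses
  is modeled.
* The size contrast ignores phylogenetic non-independence; significance
  statements are descriptive, not corrected for shared ancestry.
* Insertion specificity is purely gap-defined; a deletion in every
  background taxon is indistinguishable from a focal insertion without
  an outgroup.
* Conservation-based gene classes are computed, not curated; they will
  not coincide with hand-curated "most conserved gene" lists.
* Exact tests silently switch to approximations in the presence of ties
  at large n; the test name in every result records which path was
  taken.
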