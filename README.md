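# kuscape

Comparative-genomics tooling for the loss of classical nonhomologous end
joining (C-NHEJ) in eukaryotes and its sequence-level consequences.

C-NHEJ repairs DNA double-strand breaks by direct religation, guided by
the Ku70/Ku80 heterodimer and sealed by DNA ligase IV (Lig4). Several
parasite lineages have discarded the pathway, and genomes without it
tend to be small; trypanosomatids that additionally lost Ku accumulate
pervasive lineage-specific insertions in their protein-coding genes.
`kuscape` turns both observations into reproducible computations, for
molecular parasitologists and genome-evolution researchers who have a
presence/absence table, a species tree and a set of orthologous protein
alignments.

## What it computes

**Phyletic profiling** (`kuscape.phyletic`). From a species × {Ku70,
Ku80, Lig4} presence table: the census of genomes encoding k = 0…3
components; the genome-size contrast between pathway-lacking (all three
absent) and pathway-bearing (≥ 1 present) genomes — two-sided
Mann–Whitney U on raw sizes (exact for small untied samples) plus a
Welch t-test on log10 sizes; and, on a rooted species tree, the Dollo
parsimony minimum number of independent losses per component. Under
single origin and no regain, that minimum is the number of maximal
all-absent subtrees, and each loss is reported on the edge subtending
one.

**Insertion analysis** (`kuscape.insertions`, `kuscape.stats`). In a
protein MSA with a declared focal lineage, a column is an insertion
candidate iff some focal taxon has a residue while ≥ `bg_gap_frac` of
background taxa are gapped. Maximal candidate runs become blocks with
both alignment-column and ungapped-residue coordinates (for mapping onto
structures), filtered by a minimum focal length. Downstream statistics:
per-taxon insertion fractions (pooled and per-alignment mean), paired
Wilcoxon comparison of fractions between a focal and a reference taxon,
amino-acid composition enrichment of insertions (per-residue G-tests
with Benjamini–Hochberg correction), cross-taxon similarity of the
enrichment pattern, divergence of insertion flanks vs distal sequence,
conservation-vs-insertion-load correlation, and peptide coverage of
insertions from mass-spectrometry peptide lists.

**Synthetic data** (`kuscape.synthetic`). Generators with known ground
truth: orthogroup alignments whose focal lineage carries Poisson-placed,
geometric-length insertions (the true alignment is emitted directly, no
aligner involved), and phyletic tables whose loss probability is
logistic in log10 genome size. Detection and inference are validated
against this ground truth and against brute-force oracles.

## Worked example

Simulate study-shaped inputs and run both analyses (all outputs are
deterministic given the seed):

```sh
kuscape simulate orthogroups --n 20 --length 400 \
    --ins-rate 0.0247 --ref-ins-rate 0.0148 --seed 7 --out msa
kuscape simulate phyletic --n-species 120 --seed 7 \
    --out profile.tsv --tree-out species.nwk
kuscape phyletic --profile profile.tsv --tree species.nwk --out phyletic.json
kuscape insertions --msa-dir msa --focal jacA,jacB --reference Tbrucei \
    --out blocks.tsv --summary summary.json
```

From `phyletic.json`: the census is `{"0": 24, "3": 96}` (this generator
loses the pathway all-or-none), the mean genome size is 35.1 Mb in the
lacking group vs 707.3 Mb in the bearing group — a 20.2× ratio,
Mann–Whitney p = 2.95 × 10⁻⁹ — and Dollo needs 20 independent losses of
ku70 on the simulated tree. From `summary.json`: pooled insertion
fractions are 13.8% for each focal species (jacA, jacB) and 8.8% for the
reference (Tbrucei), i.e. the focal clade carries markedly more inserted
sequence than the reference, the comparison at the heart of the
insertion analysis. `blocks.tsv` lists each block with 1-based inclusive
column and residue coordinates:

```text
orthogroup  taxon  col_start  col_end  res_start  res_end  length_res  cand_cols
OG0000001   jacA   78         82       45         49       5           5
```

The all-in-one `kuscape run --config run.toml` executes every configured
stage and writes a JSON report embedding the resolved configuration,
package version and input checksums.

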