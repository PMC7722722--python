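# Methods

`immscape` re-implements, as a tested reusable library, the bespoke
computations of a paired tumor/adjacent single-cell immune-profiling study
design: seven patients, each contributing one tumor and one matched
adjacent-tissue sample of sorted CD45+ immune cells, with coupled
single-cell 5' expression and TCR V(D)J data. This note records the models,
conventions, and design choices; everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Data model and normalization

Counts are raw UMIs in a sparse gene × cell matrix with per-cell
annotations (patient, tissue ∈ {tumor, adjacent}, cell type, cluster).
Cluster labels are consumed, never produced: clustering, integration, and
embedding are out of scope.

Two normalization scales are used everywhere downstream:

- `log2p1`: `log2(count + 1)`, which keeps zeros at zero and sparsity
  intact;
- `zscore_log2p1`: a per-gene z-score of the log values over a chosen cell
  subset. The standard deviation is the **population** convention
  (divide by n), fixed and documented because results at small n depend on
  it; genes constant over the subset map to all-zero rows rather than
  NaNs.

## QC filter

Cells are removed when they have fewer than `min_genes` (default 400)
detected genes **or** a mitochondrial count fraction above `max_mito_frac`
(default 10%). The removal thresholds are strict inequalities, so a cell at
exactly 400 genes or exactly 10% mitochondrial counts is kept. The
mitochondrial fraction is counts on genes whose symbol starts with a
configurable prefix (default `MT-`) divided by the cell's total counts; no
fixed mitochondrial gene list is assumed. The source protocol phrases the
two conditions as a conjunction; we read them as two independent removal
rules (either one triggers removal), which matches common practice — the
thresholds are configurable if a different reading is wanted. In the QC
report a cell failing both rules is tallied once, under the low-gene rule,
keeping the report additive. The filter is idempotent.

## Signature scoring

A cell's score for a signature is the mean of its z-scored `log2p1` values
over the signature genes present in the matrix. Genes absent from the
matrix are dropped with a warning, not zero-imputed — imputation would bias
scores toward zero by an amount that varies between datasets. Duplicated
gene entries are deduplicated, so scores are invariant to gene order and
multiplicity. Cluster-level scores are means of member-cell scores,
optionally re-z-scored across clusters for dot-plot output.

Fixed signatures: the naive T-cell score uses CCR7, TCF7, LEF1, SELL. The
proliferation score is the per-cell **max** of the G1/S and G2/M phase
scores — a cell in either phase is cycling; the combination rule is our
choice, as no canonical rule exists. The phase gene lists ship as an
editable GMT fixture (`data/cell_cycle.gmt`, the widely used ~43/54-gene
phase lists) since they originate outside this package.

Anchor-derived signatures: given an anchor gene (FGFBP2 for cytotoxicity,
LAG3 for exhaustion, FOXP3 for Treg), each gene's Pearson correlation with
the anchor is computed across a caller-chosen cell subset on `log2p1`
values (Pearson is invariant to the per-gene affine map a z-score applies,
so the scale choice cannot change the ranking). The top-k genes (default
k = 50) form the signature; the anchor is excluded from its own signature;
constant genes are ineligible; ties break lexicographically. Whether the
derivation should run within a compartment (e.g. T cells only) or over all
cells is exposed as the subset argument rather than fixed.

Pairwise gene correlation (e.g. GZMK vs EOMES) is Pearson on `log2p1`
values with the two-sided t-distribution p-value at n − 2 degrees of
freedom.

## TCR clonotypes

Within each cell and locus, the **dominant** chain is the productive,
full-length contig with the highest UMI count; UMI ties break to the
lexicographically smallest CDR3 nucleotide sequence (deterministic and
data-independent). Extra productive contigs beyond the dominant one are
kept in a diagnostics table. A cell with both a dominant TRA and a dominant
TRB receives the clonotype key (α CDR3, β CDR3) scoped by patient; cells
missing either chain are unassigned. Two cells share a clonotype only if
both sequences match. Keys use CDR3 **nucleotide** sequences by default —
the strictest reading, and the granularity of the upstream V(D)J caller —
with amino-acid keys and V/J-gene inclusion available as options.

Derived analytics:

- chain recovery: fractions of the T-cell universe with a productive TRA,
  TRB, and both, reported as percentages rounded to two decimals;
- clone-size spectrum: clonotype count per size, conserving
  Σ size × count = number of assigned cells;
- clonal-expansion bins: per group, cell fractions at sizes {1, 2, ≥3};
  a cell is *clonal* when its clonotype has ≥ 2 member cells;
- sharing matrix: a clonotype is *present* in a cluster when ≥ 1 member
  carries the label; counts are presence-set intersections (symmetric,
  diagonal = cluster clonotype count); percentages divide by the **focal
  (row) cluster's** clonotype count and are deliberately asymmetric, since
  a small cluster can share most of its repertoire with a large one while
  the converse share is small.

## Ligand–receptor interactions

The score of pair (L, R) from sender type S to receiver type T in one
sample is `mean(L | S cells) × mean(R | T cells)` on the `log2p1` scale
(raw-count means are available as an option; "average expression" admits
either reading, and the log scale matches how expression is reported
elsewhere in the pipeline). Samples lacking either cell type are recorded
as absent, never as zero — spurious zeros would deflate the significance
call.

The cohort-level call applies a **one-sample, one-sided (greater than
zero) Wilcoxon signed-rank test** to the per-patient scores within a
tissue; an interaction is significant at p < α (default 0.05). Zeros are
dropped before ranking (the classic signed-rank convention); an all-zero
vector gives p = 1. For n ≤ 25 the null distribution is exact, computed by
dynamic programming over all 2ⁿ sign assignments of the (doubled, hence
integer) midranks — identical to full enumeration, and correct under ties;
above that a normal approximation with tie and continuity correction is
used. At n = 7 attainable p-values are multiples of 1/128, so the test is
conservative: with all seven scores positive p = 1/128 ≈ 0.0078, and a
call requires at least five of seven patients with nonzero scores. No
multiple-testing correction is applied to the call; the screen reports the
number of tests and a clearly separate Benjamini–Hochberg column for users
who want one.

## Composition

Per-sample unit fractions are computed against a declared denominator
(all cells, CD45+ cells, or the unit's parent lineage); fractions within a
partition sum to 1. The paired tissue test is a two-tailed paired Student's
t-test on per-patient (tumor − adjacent) fractions, with a signed-rank
variant selectable; unpaired patients are dropped with a warning and fewer
than two pairs is an error. Cross-sample PCA and all plotting are left to
the exported tidy tables.

## Synthetic cohort generator

The generator defines the study conditions every recovery experiment runs
under: 7 patients × 2 tissues × 2,000 cells per sample, a 200-gene panel,
and eight immune populations (naive CD4, CD4 effector, Treg, cytotoxic
CD8, exhausted CD8, macrophage, NK, B) whose tumor/adjacent fractions plant
the compositional shifts of an immunosuppressed tumor microenvironment
(Treg and exhausted CD8 enriched in tumor; NK and B depleted).

Counts are negative binomial with shared dispersion r = 2 and two baseline
regimes:

- ordinary "program" genes at mean 0.5 per cell, with cell-type markers
  (including the exhaustion program anchored by LAG3, the cytotoxic
  program anchored by FGFBP2, and FOXP3-led Treg markers) up-shifted
  8-fold in their type;
- sparse "signaling" transcripts — the ligand/receptor catalogue — at mean
  0.0025 per cell, so that a per-sample per-type mean is frequently
  exactly zero. This mirrors how lowly expressed cytokine/receptor
  transcripts behave in droplet data and is what makes a
  greater-than-zero call meaningful: with universally positive means every
  pair would be "significant". Under these defaults a null pair reaches
  five-of-seven nonzero scores with probability ≈ 0.01 on average
  (computed a priori from the negative-binomial zero mass), while a pair
  planted at fold 4 between macrophages and Tregs in tumor is called with
  probability ≈ 0.99.

Planted interactions (defaults IL1B→IL1R2 macrophage→Treg and
HLA-A→LILRB1 Treg→macrophage, fold 4, tumor only) act purely as mean
shifts of the ligand gene in sender-type cells and the receptor gene in
receiver-type cells of the designated tissue — sufficient because the
score uses only per-type means. Library-size variation, transcriptome-wide
co-expression structure, batch effects, and doublets are deliberately not
modeled; passing recovery tests therefore demonstrates correctness of the
computations under the stated statistical model, not robustness to those
real-data artifacts.

TCR structure: clonotypes are drawn per patient — singleton with
probability 0.6, otherwise 1 + Geometric(0.5), giving the long right tail
of real clone-size spectra in qualitative form (the exact law is not an
acceptance surface). CDR3 sequences are random 33–45-mers spelled from 16
sense codons with a deterministic two-codon patient prefix, which makes
cross-patient clonotype collisions impossible by construction (matching
the empirical absence of shared clones between patients). Each cell emits
one TRA and one TRB contig with independent dropout (defaults 25% / 15%,
chosen to resemble observed ~70%/82% per-chain recovery), and 5% of cells
receive a second, strictly lower-UMI TRA to exercise dominant-chain
selection. The truth record stores planted markers, interactions,
clonotype memberships and sizes for exact recovery tests.

Everything is deterministic given the seed; distinct seeds give distinct
cohorts.

## Problem sizes used in tests and the acceptance script

Recovery experiments run at the default conditions (2,000 cells/sample):
100 independently seeded cohorts for interaction sensitivity, 1,000 null
pairs on one cohort for calibration, and a 2,000-cell single-patient
cohort for signature separation. Unit tests use 200–500 cells per sample,
where every statistic except the sparse-signaling regime behaves
identically. Clonotype assignment is validated against an independent
brute-force reference on 200 random contig tables of up to 500 cells,
including multi-TRA cells, UMI ties, and chain dropout; the exact
signed-rank p is validated against full 2ⁿ enumeration on 1,000 random
vectors with n ≤ 10, including tied and zero entries.

## Known limitations

- The generator's independence between genes means anchor-derived
  signatures recover only planted co-programs; it cannot probe robustness
  to correlated background structure.
- The exact signed-rank call is conservative at n = 7; with heavy zero
  inflation its power drops sharply below five scoreable patients, and the
  screen flags (rather than tests) combinations with fewer than two.
- Gene identity is by case-sensitive symbol; no alias resolution.
- The command-line pipeline is a thin orchestration layer; all analytics
  live in the importable API, which is the primary interface.
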