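# Methods

This note documents the models and procedures implemented in
`patterncode`, the parameters that matter, the choices made where the
design was genuinely open, and what the synthetic-data experiments do
and do not demonstrate.

## The lineage model

The invariant early lineage is shipped as a packaged table
(`src/patterncode/data/lineage.tsv`: cell, parent, founder,
stage memberships), transcribed from Sulston-style lineage references,
not computed. Naming follows the standard convention — daughters append
a/p (anterior/posterior) or l/r (left/right) to the mother's name —
with the historical renames handled explicitly (P0 → AB + P1,
P1 → EMS + P2, EMS → MS + E, P2 → C + P3, P3 → D + P4, P4 → Z2 + Z3).
Founder labels are AB, MS, E, C, D, P4 (with Z2/Z3), and "P-line" for
the pre-founder germ-line chain P0–P3 and EMS.

The canonical stages are 1, 2, 4, 8, 15, 28, 51 and 102 cells. The
8- and 28-cell memberships are unambiguous (the 28-cell stage has
exactly 16 AB cells, 4 MS, 2 E, 4 C, D and P4). For the 15- and
51-cell stages the table fixes one consistent division order:

* 15-cell: 8 AB, MSa/MSp, Ea/Ep, Ca/Cp, P3;
* 51-cell: 32 AB, 8 MS, 4 E, 4 C (unchanged from 28), Da/Dp, P4;
* 102-cell: 64 AB, 16 MS, 8 E, 8 C, 4 D, Z2/Z3.

Other staging conventions can be supplied as a TSV through
`LineageTree.from_tsv`; every query is pure and deterministic.

**3D positions.** The packaged coordinates are a *synthetic geometry*:
founder lineages are laid out along the anterior-posterior axis (+x =
posterior) at literature-inspired base positions and each a/p division
step displaces daughters along x by a halving step (l/r along y). The
layout preserves exactly one property the stripe analysis needs — a/p
division history orders cells consistently along x — and encodes no
real embryo anatomy. Measured coordinates can be supplied as a TSV
(stage, cell, x, y, z).

## The synthetic embryo generator

The generator emulates the structure of a whole-embryo, multi-stage UMI
experiment. Expected expression for gene g in cell c of embryo e:

    E[x_gc] ∝ base_g(stage) · program_gc · batch_eg

* **Maternal deposit**: a fraction of genes (default 0.4) draw a
  log-normal baseline (ln-sd 1.0) shared by all cells, decaying by a
  retention factor (default 0.8) per stage step — early transcriptomes
  are dominated by maternal mRNA, later ones less so.
* **Zygotic programs**: the remaining genes sit at a small floor
  (default 0.005 of a maternal unit) and are shifted up by
  10^effect_size in the cells of their "on" states. Effect sizes are in
  log10 units; the default 1.0 is a tenfold shift. Each state of each
  simulated stage receives `program_size` exclusive genes, so a planted
  gene's on-set always lies within one stage. States declared
  equivalent share one program.
* **Embryo batch factor**: exp(N(0, embryo_effect_sd)) per embryo and
  gene (default 0.15) — the confounder per-embryo standardization must
  remove.
* **Sampling**: one multinomial draw per cell at a Poisson-distributed
  depth (default mean 20,000 UMIs), so column sums equal the drawn
  depth exactly and counts are Poisson-like. Mapped reads are modeled
  as depth × reads_per_umi (default 3).

A single seed determines truth construction and count sampling. The
zygotic floor default matters: the differential test excludes genes
detected in more than half of a stage's cells, and the floor together
with the depth sets the off-state detection rate. At the defaults an
off-state gene is detected in roughly a quarter to a third of cells and
stays eligible; a floor ten times higher pushes off-state detection
over the cap and removes the planted genes from the analysis entirely.

What the generator does **not** emulate: gene-length and ambient-RNA
artifacts, doublets, cell-size variation, spatial signal leakage,
bursty transcription, or realistic correlation structure among genes.
Passing tests therefore demonstrate the pipeline's statistical behavior
under its own model assumptions, not performance on real embryos.

**Named study-condition configurations.**

* `null_stage_config`: six 8-cell embryos (8 states × 6 replicate
  cells), 2,000 maternal genes, no planted effects, no batch effects,
  depth 700 with a flat baseline (ln-sd 0.3) so that essentially the
  whole panel is eligible — the fixture for false-discovery
  calibration. Its reads_per_umi is 20 (low-complexity libraries are
  duplicate-heavy), keeping cells above the mapped-read filter.
* `recovery_config`: eight 15-cell embryos, 900 genes = 400 maternal +
  300 planted (15 states × 20 genes, effect 1.0) + 200 unpatterned
  sparse zygotic genes. The null background keeps the eligible panel
  realistic: on real data most genes passing the sparseness filters are
  not patterned, and the pooled permutation threshold is derived from
  that mixture. Eight replicates per state reflect the replication
  depth a whole-embryo collection of this size yields.

## Normalization

Cells with ≤ 10,000 mapped reads are dropped (strict inequality).
Counts are scaled to 50,000 transcripts per cell, log10-transformed
with pseudocount 1 (configurable), and each gene is z-scored across the
cells of each embryo. Standardization runs on the log scale: the
differential test's range filter is stated in log10 units, so the log
layer is the primary scale. The standard deviation divisor is the
population one (divide by n; a two-cell embryo gives ±1), configurable
to the sample convention. Genes with zero variance within an embryo map
to 0 rather than being dropped, keeping matrices aligned across
embryos. Standardization is idempotent and removes multiplicative
embryo batch factors by construction; the test suite verifies that
embryo of origin is predictable from log expression but falls to chance
after standardization.

## Cell-state inference

Clustering runs per stage on standardized values restricted to marker
genes. The original curation of clusters was manual; the automated
surrogate makes the criterion explicit: repeatedly k-means the
remaining cells (k = states still unassigned), accept the cluster whose
embryo composition has the highest entropy (normalized by a uniform
spread over the stage's embryos — a genuine recurring state draws
evenly from all embryos; a batch artifact does not), remove it and
re-cluster. Ties go to the larger cluster. Cells are canonically
ordered by id before clustering, so the result is invariant to input
column order. A stage with fewer than two embryos has no composition
signal and falls back to one-shot k-means with a warning.

Annotation scores a cluster against each candidate identity as
mean(z over expected-on markers) − mean(z over expected-off markers)
and solves the one-identity-per-cluster matching greedily by descending
score with lexicographic tie-breaks (an optimal assignment is a
drop-in alternative; the greedy one is transparent and deterministic).
Candidate identities left unmatched that tie a cluster's winning score
within 0.1 standardized units join its equivalence group, named
"A/B" — this is how indistinguishable sister or cousin identities are
reported rather than forced apart. Whether annotation should use all
genes or marker genes only is not determined by the data model; the
default restricts to marker genes.

Robustness follows the leave-one-out rule: a cell is retained iff its
Pearson correlation to its own cluster's leave-one-out mean is at least
its correlation to every other cluster mean (ties retain; singletons
are retained and flagged). State transcriptomes are member means ± 
population sd per gene.

The t-SNE embedding is a fixed contract: PCA to 20 dimensions,
perplexity 50 (auto-reduced with a warning below 3×perplexity cells),
initialized from the first two principal directions scaled to unit
variance, fixed seed — repeated runs are bit-identical. Variable genes
are ranked by the Fano factor (variance/mean of tp50k values), which is
≈ 1 under Poisson counting noise at any mean, with lexicographic
tie-breaks.

## Differential expression

For each eligible gene at one stage the greedy search seeds the
super-group with the state whose cells-vs-rest t test gives the
smallest two-sided p, then repeatedly adds the state whose inclusion
most improves the p-value, stopping when no addition strictly improves
it. The partition's higher-mean side is "on". p along the path is
non-increasing by construction, and p\* can never exceed the best
singleton's p. The search is local: it can stop one step short of the
global optimum on rare noise configurations (measured: it attains the
brute-force optimum in ≈ 98% of strongly separated planted instances
at 5 states × 3 cells).

**Eligibility.** A gene must be detected (count > 0) in at most 50% of
the stage's cells and span at least 0.75 log10 units between its
maximum and minimum log10(tp50k+1) value at the stage. Both boundaries
are sharp (51% expressed is excluded; a range of 0.74 is excluded).

**Test variant.** The default two-sample test is the classic pooled
variance Student t (df = n1+n2−2); Welch's unequal-variance t is
available (`test="welch"`). Pooled variance is the deliberate default
for this data shape: the partitions under test are small expressing
groups against a large, mostly silent remainder. Welch's
Satterthwaite df is capped near the expressing-group size for genuine
partitions (bounding attainable significance at ~1e-7 with 8
replicates) while degenerate near-constant splits explored by the
permutation null receive df ≈ n−1 and p-values orders of magnitude
smaller — under Welch the null threshold undercuts every true call and
power collapses. Degenerate moments are handled explicitly: fewer than
two samples on a side gives p = 1; a zero standard error gives p = 1
for equal means and p = 0 for perfect separation.

**Permutation threshold.** The stage threshold τ is the ⌈fdr·n⌉-th
smallest p\* over n shuffles (default 10,000; the desk-scale
experiments use 2,000) of the cell-to-state assignment, with genes
drawn round-robin from the eligible panel so the null pools gene
behavior (per-gene calibration is available). Shuffles permute
assignments *within each embryo*: standardization ties the cells of an
embryo together (their z-values sum to zero per gene), so only cells of
the same embryo are exchangeable under the null, and a stage-wide
shuffle measurably mis-calibrates the threshold (2.6% calls at nominal
1% on fully null data, versus ~1% for the within-embryo scheme).
Within-embryo permutation preserves state sizes whenever whole embryos
are collected. Fewer than 100 shuffles is refused (the 1% quantile is
unstable).

## TF-family enrichment

For a state expressing n TFs of which k belong to a family of size K in
a universe of N annotated TFs, both inclusive cumulative tails are
computed exactly: p_enr = P(X ≥ k) and p_dep = P(X ≤ k),
X ~ Hypergeom(N, K, n). The smaller tail picks the branch; the signed
score is ±(−log10 p). Both tails include P(X = k), so they always
overlap (p_enr + p_dep ≥ 1) and exact ties resolve to the enrichment
branch. The default universe is the full annotation table; a
stage-restricted universe is selectable. The repertoire-level worked
examples assume a universe of 934 TFs with 97 homeodomains — the only
repertoire counts available — and under that assumption give
p = 1.97e-4 (7 of 14, enrichment) and p = 1.8e-2 (2 of 69, depletion);
the exact universe behind the published values of 1.5e-4 and 1e-2 is
not recorded, so agreement is at order of magnitude.

Lineage-by-stage aggregation is a two-sample Welch t test of a
family's signed scores for the states of one founder lineage at one
stage against all other scored states; groups with fewer than two
states on either side, or constant scores on both sides, report NaN.
Equivalence-group states ("A/B") follow their first named identity's
founder.

## Stripe patterning

Binary on/off calls are pushed down from states to their member cells
(equivalence-group members share values). Within one founder lineage,
cells are clustered by k-means on their raw 0/1 vectors (Euclidean,
monotone in Hamming distance; k = 8 for the AB lineage by default,
fixed seed, 10 restarts). If fewer distinct binary codes than k exist,
the code classes are used and the largest are split along the
anterior-posterior axis until k clusters exist (flagged). Clusters are
relabeled 1..k by ascending mean x, and each stripe's signature is the
set of genes on in at least half its members. The lineage-diagram
rendering is a serializable structure (gene → branch on/off, plus
parent edges) that round-trips losslessly; a matplotlib rendering is
provided for interactive use only.

## Pipeline

One flat YAML config holds every path and parameter; unknown keys are
rejected, and each run writes its resolved config and a structured log
next to the outputs. A single seed derives all per-stage seeds. Input
validation distinguishes errors (unreadable counts, marker identities
unknown to the lineage) from warnings (annotated TFs absent from the
counts). Stage execution order is preprocess → state inference →
differential expression → enrichment → stripes; any failure aborts with
the stage named. Reruns with the same config and inputs are
bit-identical up to the output directory path recorded in the resolved
config and wall times in the log.

## Desk-scale experiment sizes

The test and acceptance experiments are sized to run in seconds to
minutes on one CPU as the package's own standard configurations: 2,000
calibration shuffles (the 1% quantile of 2,000 draws carries ~±0.3
relative error, ample for a threshold), 2,000-gene null panels, 900-gene
recovery panels, and 100-instance oracle sweeps. All of them scale up by
changing one config field.

## Known limitations

* The greedy search is a local optimizer; its calls carry no guarantee
  of global optimality (measured ≈ 98% agreement with brute force under
  strong separation).
* The iterative-acceptance entropy criterion is an explicit surrogate
  for what was originally manual curation; on data with systematic
  per-embryo cell losses its uniform-composition assumption weakens.
* The hypergeometric universe is whatever annotation table is supplied;
  scores across states with very different TF counts are comparable
  only through the aggregation test, not individually.
* The simulator's independence assumptions (genes, cells) make
  permutation calibration cleaner than on real data, where gene-gene
  correlation inflates the variance of the empirical call rate.
* Synthetic 3D positions order cells by division history only; stripe
  geometry on real embryos requires measured coordinates.
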