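# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `primkit`. Everything stated here is either a design
decision or a property that the test suite / `scripts/acceptance.py`
computes; no empirical claim is made beyond what those runs measure.

## Coordinates and interval algebra

All genomic coordinates are 0-based half-open internally. BED and bedGraph
are native; GTF (1-based inclusive) is converted on read. Overlap means at
least one shared base, so touching spans (`[0,10)` vs `[10,20)`) never
overlap, never merge activity, and never contribute a TF-peak count. The
merge rule measures edge-to-edge separation: intervals whose gap
(`next.start − prev.end`) is ≤ the threshold are united, so touching or
overlapping intervals always merge. Merging is idempotent and
order-independent, and extending interior intervals by `f` then merging with
gap `g` equals merging the originals with gap `g + 2f` — both facts are
property-tested, and the whole engine (merge, extend, overlap query,
enhancer calling) is cross-checked against independent quadratic brute-force
scans on randomized instances.

Coverage is stored as a piecewise-constant step function per chromosome
(sorted, non-overlapping records with a precomputed cumulative integral), so
a mean-depth query over any window is O(log n) and memory stays linear in
the number of records rather than in genome size. Gaps read as depth 0;
overlapping records are rejected at load time.

## Promoters, states and PRIM

A promoter is `[TSS − flank, TSS + flank)` with `flank = 2000` bases,
clamped at chromosome boundaries. One promoter is kept per gene, anchored at
the canonical transcript — the longest, with ties broken toward the lowest
txStart and then the lexicographically smallest transcript id, so the choice
is deterministic. Gene-level promoters (rather than one promoter per
transcript) keep the downstream state and PRIM tables unambiguous.

Per sample, the state code is `1` when ≥ 1 K4me3 peak overlaps the promoter
and no K27me3 peak does, `0` when both marks overlap, `-1` for K27me3 only,
and `NA` for neither. A gene is consensus-bivalent in a cell type when coded
`0` in at least `min_support = 2` replicates. The cell-type-level state used
by the transition classifier generalizes the same rule to both marks: a mark
is present when seen in ≥ `min_support` replicates, and the consensus state
is re-coded from the two presence calls. With two replicates this requires
both to agree; with three it is a majority vote per mark.

PRIM is `log2((K4me3 + a)/(K27me3 + a))` with pseudocount `a = 0.001`. The
two signals are reads-per-million-scaled mean depths over the promoter
window (`mean depth × 10⁶ / library size`); depth normalization is applied
before the ratio because raw counts would confound library size between the
two marks. Cell-type PRIM averages replicate signals per mark before taking
one ratio (ratio of means), which is more stable at low counts than a mean
of ratios. PRIM is defined exactly where the state is not `NA`; the
statistic is antisymmetric in its arguments and strictly monotone in each,
and the pseudocount keeps it finite for all non-negative inputs. No
input-chromatin subtraction is performed — input enters only upstream, in
peak calling, which this package deliberately does not re-implement.

## PRIM cutoffs and the transition taxonomy

The per-cell-type threshold that separates epigenetically active from
repressive promoters is derived from labels the state coding already
provides: active = univalent K4me3 (state 1), repressive = any
K27me3-containing state (0 or −1). The cutoff maximizes Youden's J
(TPR − FPR) for the rule "active iff PRIM > c", scanning midpoints of
adjacent sorted unique PRIM values; ties take the smallest candidate, making
the result invariant to input order. The reported quality is the maximal J
(1.0 exactly when the classes are linearly separable). This label-driven
rule is a reproducible, parameter-free stand-in for a manually chosen
per-cell-type threshold; it is a design choice of this package, not a
reconstruction of any particular published procedure.

Promoter status in a cell type is `active` (state ≠ NA and PRIM > cutoff),
`repressive` (state ≠ NA and PRIM ≤ cutoff) or `unmodified` (state = NA).
The SSC→MASC decision table, per expression class:

| class | category   | condition |
|-------|------------|-----------|
| I     | Stable_I   | repressive(SSC) ∧ repressive(MASC) |
| I     | Active     | repressive(SSC) ∧ active(MASC) ∧ MASC state = K4-only |
| I     | Modified   | unmodified(SSC) ∧ MASC state ≠ NA |
| II    | Repressive | active(SSC) ∧ repressive(MASC) ∧ MASC state carries K27me3 |
| II    | Stable_II  | repressive(SSC) ∧ repressive(MASC) |
| II    | Unmodified | SSC state ≠ NA ∧ MASC state = NA |
| both  | Other      | anything else |

"Decreased K4me3" in the Repressive definition is implied by PRIM crossing
below the cutoff rather than tested separately, keeping the classifier a
function of (state, PRIM) only. `Other` absorbs combinations the named
categories do not cover (e.g. class I active→active); the named categories
are strict subsets of each class. A PRIM defined where the state is NA (or
vice versa) indicates inconsistent input tables and raises an error rather
than guessing.

## PCA and correlations in PRIM space

Sample-level PCA restricts to promoters with defined PRIM in **every**
sample (intersection, no imputation — any imputation scheme would be an
invention), mean-centers each promoter across samples, and projects samples
onto the top three components (full SVD, deterministic up to component
sign). Variance fractions are reported alongside the coordinates. Pairwise
PRIM correlation is Pearson's r over genes defined in both samples, and the
direction-bias comparison of up/down counts between gene groups is a
one-sided Fisher exact test.

## Expression classes

Differential genes among SSC, MASC and ESC satisfy |log2FC| ≥ 1 (two-fold)
and P < 0.05 in at least one pairwise comparison; log2FC is the difference
of cell-type means of log2 expression and P comes from Welch's two-sample
t-test on replicate values. The Welch test substitutes for a
moderated-statistics fit; the selection rule itself is unchanged. No
multiplicity adjustment is applied (the joint fold+significance gate is the
filter). Note that Welch's test at n = 3 per group is conservative: its true
type-I level is ≈ 0.035 at the 0.05 nominal level, which the acceptance
measurements estimate on a large pure-noise matrix.

Selected genes are clustered agglomeratively: rows mean-centered ("centered
on gene"), gene–gene distance 1 − uncentered correlation across samples,
centroid linkage with centroids the unweighted means of member rows of the
centered matrix. Because standard linkage implementations restrict centroid
linkage to Euclidean distance, the agglomeration is implemented directly,
with equal-distance merges broken toward the lexicographically smallest
active cluster pair so the tree is reproducible. Cutting at the root gives
the two-way partition; the branch with the higher MASC+ESC minus SSC mean is
class I, the other class II, and a degenerate run in which both branches
shift the same way raises an error.

## Enhancer landscape

Enhancer calling is a two-stage rule cascade. Per cell type: extend that
cell type's K4me3 peaks by 1 kb each way; discard K27ac peaks overlapping an
extended K4me3 peak, any gene body `[txStart, txEnd)`, or any TSS/TES
coordinate (realized as 1-bp point intervals — since txEnd is exclusive, the
base at txEnd lies outside the body and is excluded explicitly); merge
survivors with gap ≤ 500 bp. Then pool the per-cell-type sets and merge
again with the same gap. Exclusion uses each cell type's own K4me3 peaks by
default; a switch (`k4_union`) filters against the union across cell types
instead. Rejection is peak-level, not trimming: a K27ac peak touching an
exclusion zone by one base is removed entirely.

Activity flags come from ≥ 1-base overlap with each cell type's K27ac peaks;
elements active nowhere are dropped, and the subset label concatenates the
initials of active cell types in fixed S, M, E order, so the seven labels
partition the catalog. Gene association lists all transcripts whose txStart
or txEnd lies within 100 kb of the element (distance 0 when the element
overlaps the transcript span), and an element near both a class I and a
class II gene counts toward both fractions. Empty subsets report undefined
(NaN) fractions, never zero. TF-peak counting is a plain overlap count per
(region, factor).

## TSS profiles

Profile matrices hold reads-per-million mean depth in 100-bp bins over
TSS ± 2 kb (matching the promoter window); bins of minus-strand genes are
reversed so bin 0 is always most upstream, and windows truncated by a
chromosome edge read the missing bases as depth 0. For clustering, each
(sample, mark) block is divided by its global mean — a simple linear
normalization that puts marks of different intensity on comparable scale —
and the blocks are concatenated per gene. K-means runs with a fixed seed and
100 restarts, keeping the best-inertia solution; identical inputs with the
same seed give identical assignments, and a solution with an empty cluster
or duplicate centroids is flagged as degenerate rather than hidden. The
number of clusters k is a required user parameter (default 2 in the
pipeline configuration). Group comparisons use the per-gene mean over bins
and a two-sided Wilcoxon rank-sum test (exact for small tie-free samples,
normal approximation with tie correction otherwise); groups with fewer than
3 genes get summary statistics but no test.

## Synthetic study generator

The generator emits a complete miniature study in the same formats the
pipeline reads, with planted ground truth for every stage. Defaults (the
study conditions used throughout the tests): 2 chromosomes × 10 Mb, 1,000
genes placed non-overlapping with ≥ 10 kb spacing and random strand, three
cell types (SSC, MASC, ESC) with 3/2/2 ChIP replicates and 3 RNA replicates.

* **States.** Per (gene, cell type), drawn from per-cell-type proportions
  {K4-only 0.45, bivalent 0.25, K27-only 0.02, unmodified 0.28}, chosen so
  bivalent promoters dominate the K27me3-marked fraction (~0.93) as expected
  for germline-like cells. 74 class I and 91 class II genes (≈ 1/10 study
  scale) get forced SSC/MASC state pairs realizing target transition-category
  mixes (Stable_I 0.145, Active 0.135, Modified 0.054 within class I;
  Repressive 0.486, Stable_II 0.09, Unmodified 0.10 within class II; rest
  Other).
* **Coverage.** Negative-binomial per 100-bp bin (variance μ + 0.3 μ²;
  overdispersion is the realistic choice for ChIP-seq), background mean 1.0,
  ×8 enrichment over promoters of marked genes; replicates are independent
  redraws sharing the planted state. Dispersion 0 switches to deterministic
  coverage equal to the mean — the noise-free limit. Library size is the
  integral of the track.
* **Peaks.** Promoter windows of marked genes, with whole-peak drop
  (false-negative 0.05) and insert (false-positive 0.05) noise per replicate
  — peak-caller error is modeled at the whole-peak level because all
  downstream logic is overlap-based.
* **Expression.** log2 values: per-gene baseline N(4, 1.5²), planted effect
  +2 (class I) or −2 (class II) in MASC and ESC, residual noise N(0, 0.5²).
* **Enhancers.** ~182 elements with fixed per-pattern counts
  (S 45, M 15, E 59, SM 5, SE 10, ME 30, SME 18; ≈ 1/27 study scale),
  placed intergenic with ≥ 3.5 kb clearance from gene spans (covering
  promoter K4me3 peaks plus their 1-kb extension) and ≥ 2 kb apart so no two
  planted elements merge; per-cell-type K27ac peaks equal the element spans.
  Enhancer peaks carry no caller noise by default (a separate knob exists).

All randomness flows from one seed through independent child streams, so
identical configurations produce byte-identical outputs. At zero noise the
pipeline provably recovers the planted truth exactly — states, consensus
bivalent sets, transition categories and enhancer partitions — which the
acceptance measurements verify; under the default noise model transition
recovery stays ≥ 80% (measured ≈ 95–97%).

**What the simulator does not model**, and hence what passing tests do not
show about real data: read-level artefacts (mappability, GC bias, duplicate
reads, fragment-length effects), broad/diffuse K27me3 domains wider than the
promoter window, correlated replicate failures, batch effects between
laboratories, overlapping genes and alternative promoters, peak boundaries
that differ from promoter windows, and copy-number or input-chromatin
structure. Results on real data additionally depend on the upstream
aligner/peak-caller choices that are outside this package's scope.

## Pipeline and determinism

The pipeline persists every stage output as TSV/BED under the output
directory and writes `summary.json` with sorted keys, so re-running with the
same inputs and seed is byte-identical (PCA coordinates, whose component
signs are arbitrary, are persisted as TSV but only sign-free variance
fractions enter the summary). Each stage reads its inputs from the persisted
intermediates when invoked alone, so a single-stage re-run equals the
full-run result for that stage. Stages whose inputs are absent (no K27ac
samples, no expression table) are skipped with an explicit notice in the
summary; a stage failure aborts the run naming the stage, and already
written outputs are retained. Logging goes to stderr and `run.log`, with
SHA-256 digests of the inputs recorded in the summary.

Problem sizes throughout the tests and acceptance script — 1,000-gene
noise-free and noisy studies, a 500-gene expression-recovery run, a
12,000-gene null for gate calibration, 500-instance oracle sweeps — are the
package's chosen desk-scale study conditions; the full pipeline on the
default study runs in seconds.

## Known limitations

* The PRIM cutoff rule is a principled substitute for a manual per-cell-type
  threshold choice, not a reconstruction of one; cutoffs on real data should
  be inspected against the PRIM distribution.
* Welch's t at 2–3 replicates is conservative and under-powered relative to
  moderated-variance tests; with three replicates per group, recovery of a
  2-fold effect at residual sd 0.5 is ≈ 93–97%, not 100%.
* One canonical promoter per gene: alternative promoters are out of scope.
* The profile normalization (block/global-mean scaling) is one reasonable
  linear scheme among several; cluster shapes, not absolute levels, are the
  intended signal.
* No FDR control on the differential gate: the joint fold+significance
  filter is itself the selection rule, by design.
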