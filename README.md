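# primkit

Integrative promoter/enhancer chromatin-state analysis for stem-cell
reprogramming studies, built around the **PRIM** statistic — the promoter
ChIP-seq read-intensity ratio for histone modification.

## The scientific problem

Mouse spermatogonial stem and progenitor cells (SSCs) are unipotent, yet in
long-term culture they spontaneously convert into multipotent adult
spermatogonial-derived stem cells (MASCs) that behave much like embryonic
stem cells (ESCs). A central question is how the SSC epigenome encodes this
plasticity. The analysis implemented here integrates histone-modification
ChIP-seq (H3K4me3, H3K27me3, H3K27ac) with RNA-seq across SSC, MASC and ESC
to ask, per promoter and per enhancer, what changes during reprogramming.

The package is aimed at computational biologists who have peak calls (BED),
normalized coverage tracks (bedGraph), a transcript annotation (GTF or
refFlat-like TSV) and a log2-FPKM expression table, and who want a tested,
scriptable re-implementation of this analysis — plus a synthetic study
generator with planted ground truth, so every stage can be validated without
touching real sequencing data.

## The model

**Promoter states.** A promoter is TSS ± 2 kb of a gene's canonical
transcript. From one sample's peak calls each promoter is coded
`1` (K4me3 only), `0` (K4me3 + K27me3, *bivalent* — a poised state),
`-1` (K27me3 only) or `NA` (unmodified). A gene is called bivalent in a cell
type when it is coded `0` in at least two biological replicates.

**PRIM.** The epigenetic likelihood of transcription at a promoter is
summarized as

```
PRIM = log2( (K4me3 + a) / (K27me3 + a) ),   a = 0.001
```

where K4me3 and K27me3 are the reads-per-million-scaled mean read depths
over the promoter window (replicates averaged per mark before the ratio).
PRIM is evaluated only at promoters with a detectable K4me3 or K27me3 peak.
A per-cell-type cutoff, chosen to best separate univalent-K4me3 (active)
from K27me3-containing (repressive) promoters by Youden's J, splits
PRIM-high from PRIM-low promoters.

**Transition taxonomy.** Differentially expressed genes (≥ 2-fold, P < 0.05
in any pairwise Welch test among SSC/MASC/ESC) are split by hierarchical
clustering into class I (activated in MASC and ESC) and class II
(repressed). Within each class, the SSC→MASC change in (state, PRIM) assigns
each promoter one of the named transition categories: Stable I, Active,
Modified (class I); Repressive, Stable II, Unmodified (class II); plus Other.

**Enhancers.** Intergenic K27ac+/K4me3− elements: per cell type, K4me3 peaks
are extended 1 kb each way; K27ac peaks overlapping an extended K4me3 peak,
a gene body, or a TSS/TES position are discarded; survivors within 500 bp
are merged; the per-cell-type sets are pooled and merged again. Overlap with
a cell type's K27ac peaks makes an element *active* there, giving the
seven-way S/M/E/SM/SE/ME/SME partition and, via all transcripts within
100 kb, the association with class I/II genes.

**Profiles.** TSS-centered read-density matrices (±2 kb, 100-bp bins,
minus-strand reversed) feed seeded k-means to group bivalent promoters by
K4me3/K27me3 profile shape, with two-sided Wilcoxon rank-sum tests between
gene groups.

## Worked example

Generate a synthetic study (400 genes, two 10-Mb chromosomes, planted
promoter states, expression classes and enhancer activity patterns), then
run the full pipeline:

```sh
primkit simulate --out demo --seed 7 --genes 400
primkit run-all --config demo/pipeline.yaml
```

`demo/results/summary.json` then contains (abridged):

```json
{
  "bivalent_fraction_of_k27": {"SSC": 0.944, "MASC": 0.853, "ESC": 0.780},
  "consensus_bivalent_counts": {"SSC": 102, "MASC": 99, "ESC": 78},
  "prim_cutoffs": {
    "SSC":  {"threshold": 1.121, "quality": 0.990},
    "MASC": {"threshold": 1.147, "quality": 0.939},
    "ESC":  {"threshold": 0.109, "quality": 0.967}
  },
  "expression": {"n_selected": 66, "n_class_I": 30, "n_class_II": 36},
  "transitions": {"Stable_I": 6, "Active": 4, "Repressive": 15,
                  "Stable_II": 6, "Unmodified": 3, "Other": 32},
  "enhancers": {"n_total": 182,
                "subsets": {"S": 45, "M": 15, "E": 59, "SM": 5,
                            "SE": 10, "ME": 30, "SME": 18}},
  "profiles": {"n_genes": 102, "k": 2, "cluster_sizes": {"0": 71, "1": 31}}
}
```

Reading this output: 94% of K27me3-marked SSC promoters are bivalent (the
hallmark of a poised germline-like epigenome); 66 genes are differentially
expressed and split into 30 activated (class I) and 36 repressed (class II)
genes; the transition counts say, e.g., that 15 class II promoters gained
K27me3 de novo in MASC (Repressive) while 3 lost all modification
(Unmodified); and the 182 enhancers partition into the seven activity
subsets, here exactly the planted design because the demo is noise-free.
The per-cell-type PRIM cutoffs separate active from repressive promoters
with near-perfect quality (Youden's J ≈ 0.94–0.99).

Every stage is also callable as a library function (`primkit.compute_prim`,
`primkit.call_enhancers`, `primkit.classify_transitions`, ...) and as a
single-stage subcommand (`primkit prim --config ...`,
`primkit enhancers --config ...`) that re-runs one stage from the persisted
intermediates.

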