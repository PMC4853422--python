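"""Synthetic miniature study with planted ground truth.

Emulates the statistical structure of a promoter/enhancer chromatin-state
study of SSC reprogramming: a small genome with non-overlapping genes;
per-cell-type planted promoter states over {K4-only, bivalent, K27-only,
unmodified}; negative-binomial ChIP coverage with fold enrichment over
marked promoters; peak calls equal to promoter windows of marked genes,
perturbed by whole-peak drop/insert noise; a log2 expression matrix with
planted two-fold class I/II effects; and intergenic enhancers with planted
per-cell-type activity patterns. Everything is deterministic for a fixed
seed, and with all noise rates at zero every downstream stage recovers the
planted truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .intervals import (
    CoverageTrack,
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    TranscriptAnnotation,
)
from .promoters import STATE_DTYPE

NA_STATE = "NA"
PEAK_SCORE = 5.0  # the upstream caller's significance convention, opaque here

# Transition categories are planted through forced (SSC, MASC) state pairs.
# PRIM separates K4-only (high) from K27me3-containing (low) promoters, so
# the state pair determines the recovered category at zero noise.
_CLASS_I_STATES = {
    "Stable_I": (0, 0),
    "Active": (0, 1),
    "Modified": (None, 1),
    "Other": (1, 1),
}
_CLASS_II_STATES = {
    "Repressive": (1, 0),
    "Stable_II": (0, 0),
    "Unmodified": (1, None),
    "Other": (None, -1),
}


def _default_state_proportions() -> dict[str, dict]:
    # bivalent dominates K27me3-marked promoters (~0.93 of them), mirroring
    # the germline-like cell types under study
    base = {1: 0.45, 0: 0.25, -1: 0.02, NA_STATE: 0.28}
    return {"SSC": dict(base), "MASC": dict(base), "ESC": dict(base)}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator (desk scale)."""

    seed: int = 0
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (2000, 8000)
    gene_spacing: int = 10_000
    chip_replicates: dict[str, int] = field(
        default_factory=lambda: {"SSC": 3, "MASC": 2, "ESC": 2}
    )
    state_proportions: dict[str, dict] = field(
        default_factory=_default_state_proportions
    )
    # transition design: DE gene counts and category mixes, ~1/10 study scale
    n_class_i: int = 74
    n_class_ii: int = 91
    class_i_categories: dict[str, float] = field(
        default_factory=lambda: {
            "Stable_I": 0.145, "Active": 0.135, "Modified": 0.054, "Other": 0.666,
        }
    )
    class_ii_categories: dict[str, float] = field(
        default_factory=lambda: {
            "Repressive": 0.486, "Stable_II": 0.09, "Unmodified": 0.10, "Other": 0.324,
        }
    )
    # coverage model
    promoter_flank: int = 2000
    background_mean: float = 1.0
    enrichment_fold: float = 8.0
    dispersion: float = 0.3  # NB: var = mu + dispersion * mu^2; 0 = deterministic
    coverage_bin: int = 100
    # peak-call noise (whole-peak drop / insert per replicate)
    false_negative_rate: float = 0.05
    false_positive_rate: float = 0.05
    # expression model (log2 units)
    rna_replicates: int = 3
    baseline_mean: float = 4.0
    baseline_sd: float = 1.5
    effect: float = 2.0
    noise_sd: float = 0.5
    # enhancer design
    enhancer_counts: dict[str, int] = field(
        default_factory=lambda: {
            "S": 45, "M": 15, "E": 59, "SM": 5, "SE": 10, "ME": 30, "SME": 18,
        }
    )
    enhancer_length_range: tuple[int, int] = (400, 1500)
    enhancer_spacing: int = 2000
    enhancer_clearance: int = 3500
    enhancer_fn: float = 0.0

    def __post_init__(self) -> None:
        for ct, props in self.state_proportions.items():
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"state proportions for {ct} must sum to 1")
        for rates in (self.false_negative_rate, self.false_positive_rate,
                      self.enhancer_fn):
            if not 0 <= rates <= 1:
                raise ValueError("noise rates must lie in [0, 1]")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment fold must exceed 1 (states undetectable)")

    def noise_free(self) -> "SimulationConfig":
        return replace(
            self,
            false_negative_rate=0.0,
            false_positive_rate=0.0,
            enhancer_fn=0.0,
            dispersion=0.0,
        )

    @property
    def cell_types(self) -> list[str]:
        return list(self.chip_replicates)


@dataclass
class GroundTruth:
    """Planted states, classes, categories and enhancer patterns."""

    states: pd.DataFrame  # genes x cell types, nullable Int8
    expression_class: pd.Series  # gene -> "I"/"II", NA for null genes
    transition_category: pd.Series  # gene -> category, NA for null genes
    enhancers: pd.DataFrame | None = None  # chrom, start, end, pattern, linked_gene


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    layout: GenomeLayout
    annotation: list[TranscriptAnnotation]
    chip_peaks: dict[tuple[str, int, str], PeakSet]  # (ct, rep, mark)
    coverage: dict[tuple[str, int, str], CoverageTrack]
    k27ac_peaks: dict[str, PeakSet]  # per cell type (pooled)
    expression: ExpressionTable
    truth: GroundTruth


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[GenomeLayout, list[TranscriptAnnotation]]:
    """Place one-transcript genes non-overlapping with >= spacing between."""
    layout = GenomeLayout(config.chromosomes)
    chroms = list(layout)
    total_len = sum(layout.values())
    # genes per chromosome, proportional to length
    counts = [int(round(config.n_genes * layout[c] / total_len)) for c in chroms]
    counts[-1] += config.n_genes - sum(counts)
    lo, hi = config.gene_length_range
    transcripts: list[TranscriptAnnotation] = []
    gene_no = 0
    for chrom, n in zip(chroms, counts):
        if n == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n)
        needed = int(lengths.sum()) + (n + 1) * config.gene_spacing
        if needed > layout[chrom]:
            raise ValueError(
                f"{chrom}: cannot place {n} genes with {config.gene_spacing}-bp "
                f"spacing in {layout[chrom]} bases"
            )
        slack = layout[chrom] - needed
        cuts = np.sort(rng.uniform(0, slack, size=n)).astype(np.int64)
        cursor = 0
        for k in range(n):
            start = config.gene_spacing * (k + 1) + cursor + int(cuts[k])
            end = start + int(lengths[k])
            cursor += int(lengths[k])
            gene_no += 1
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(
                TranscriptAnnotation(
                    transcript_id=f"tx{gene_no:05d}",
                    gene_id=f"gene{gene_no:05d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                )
            )
    return layout, transcripts


def _plant_states(
    config: SimulationConfig,
    genes: list[str],
    rng: np.random.Generator,
) -> GroundTruth:
    """Draw per-cell-type states and force transition-design state pairs."""
    cts = config.cell_types
    n = len(genes)
    states = pd.DataFrame(index=pd.Index(genes, name="gene"), columns=cts,
                          dtype=object)
    for ct in cts:
        props = config.state_proportions[ct]
        codes = list(props)
        draws = rng.choice(len(codes), size=n, p=[props[c] for c in codes])
        states[ct] = [codes[d] for d in draws]
    n_de = config.n_class_i + config.n_class_ii
    if n_de > n:
        raise ValueError("more designed DE genes than genes")
    de_idx = rng.choice(n, size=n_de, replace=False)
    class_label = pd.Series(pd.NA, index=states.index, dtype=object)
    category = pd.Series(pd.NA, index=states.index, dtype=object)

    def _assign(idx: np.ndarray, cls: str, mix: dict[str, float],
                state_map: dict[str, tuple]) -> None:
        cats = list(mix)
        draws = rng.choice(len(cats), size=len(idx), p=[mix[c] for c in cats])
        for gi, d in zip(idx, draws):
            cat = cats[d]
            ssc, masc = state_map[cat]
            gene = genes[gi]
            class_label[gene] = cls
            category[gene] = cat
            states.at[gene, "SSC"] = NA_STATE if ssc is None else ssc
            states.at[gene, "MASC"] = NA_STATE if masc is None else masc

    _assign(de_idx[: config.n_class_i], "I", config.class_i_categories,
            _CLASS_I_STATES)
    _assign(de_idx[config.n_class_i:], "II", config.class_ii_categories,
            _CLASS_II_STATES)
    # to nullable integer coding
    coded = states.replace(NA_STATE, pd.NA).astype(STATE_DTYPE)
    return GroundTruth(
        states=coded, expression_class=class_label, transition_category=category
    )


def _promoter_interval(
    tx: TranscriptAnnotation, flank: int, layout: GenomeLayout
) -> GenomicInterval:
    start = max(0, tx.tss - flank)
    end = min(layout[tx.chrom], tx.tss + flank)
    return GenomicInterval(tx.chrom, start, end)


def _nb_draw(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson-like at 0)."""
    if dispersion == 0:
        return mu.copy()
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(float)


def simulate_chromatin(
    config: SimulationConfig,
    annotation: Sequence[TranscriptAnnotation],
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> tuple[
    dict[tuple[str, int, str], CoverageTrack],
    dict[tuple[str, int, str], PeakSet],
    GroundTruth,
]:
    """Coverage tracks, peak sets and planted states per (cell type, replicate).

    Coverage is NB background times the enrichment fold over promoters of
    marked genes (shared across replicates through the planted state);
    peaks are the promoter windows of marked genes with whole-peak
    drop/insert noise applied independently per replicate.
    """
    genes = [tx.gene_id for tx in annotation]
    truth = _plant_states(config, genes, rng)
    by_gene = {tx.gene_id: tx for tx in annotation}
    bin_w = config.coverage_bin
    mark_states = {"K4me3": (1, 0), "K27me3": (0, -1)}
    coverage: dict[tuple[str, int, str], CoverageTrack] = {}
    peaks: dict[tuple[str, int, str], PeakSet] = {}
    for ct in config.cell_types:
        col = truth.states[ct]
        for mark, carrying in mark_states.items():
            has_mark = col.isin(carrying).fillna(False)
            marked = [g for g in genes if has_mark[g]]
            marked_ivs = {
                g: _promoter_interval(by_gene[g], config.promoter_flank, layout)
                for g in marked
            }
            # per-chromosome mean-depth template shared by the replicates
            mu_by_chrom: dict[str, np.ndarray] = {}
            for chrom, length in layout.items():
                n_bins = length // bin_w
                mu = np.full(n_bins, config.background_mean)
                for iv in marked_ivs.values():
                    if iv.chrom != chrom:
                        continue
                    b0 = iv.start // bin_w
                    b1 = -(-iv.end // bin_w)
                    mu[b0:b1] = config.background_mean * config.enrichment_fold
                mu_by_chrom[chrom] = mu
            for rep in range(1, config.chip_replicates[ct] + 1):
                records = {}
                total = 0.0
                for chrom, mu in mu_by_chrom.items():
                    vals = _nb_draw(mu, config.dispersion, rng)
                    starts = np.arange(len(mu), dtype=np.int64) * bin_w
                    ends = starts + bin_w
                    records[chrom] = (starts, ends, vals)
                    total += float(vals.sum()) * bin_w
                sample_id = f"{ct}_rep{rep}"
                coverage[(ct, rep, mark)] = CoverageTrack(
                    sample_id, mark, records, library_size=max(1, round(total))
                )
                kept: list[GenomicInterval] = []
                for g in genes:
                    iv = _promoter_interval(
                        by_gene[g], config.promoter_flank, layout
                    )
                    if has_mark[g]:
                        if rng.random() >= config.false_negative_rate:
                            kept.append(
                                GenomicInterval(
                                    iv.chrom, iv.start, iv.end, score=PEAK_SCORE
                                )
                            )
                    elif config.false_positive_rate and (
                        rng.random() < config.false_positive_rate
                    ):
                        kept.append(
                            GenomicInterval(
                                iv.chrom, iv.start, iv.end, score=PEAK_SCORE
                            )
                        )
                peaks[(ct, rep, mark)] = PeakSet(sample_id, ct, mark, kept)
    return coverage, peaks, truth


def simulate_expression(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> ExpressionTable:
    """log2 expression with planted +/- `effect` for class I/II in MASC and ESC."""
    if config.rna_replicates < 2:
        raise ValueError("need >= 2 RNA replicates per cell type")
    genes = truth.states.index
    base = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    effect = np.zeros(len(genes))
    effect[(truth.expression_class == "I").to_numpy()] = config.effect
    effect[(truth.expression_class == "II").to_numpy()] = -config.effect
    cols = {}
    groups = {}
    for ct in ("SSC", "MASC", "ESC"):
        shift = effect if ct in ("MASC", "ESC") else 0.0
        for rep in range(1, config.rna_replicates + 1):
            name = f"{ct}_rna{rep}"
            cols[name] = base + shift + rng.normal(0, config.noise_sd, len(genes))
            groups[name] = ct
    values = pd.DataFrame(cols, index=genes)
    return ExpressionTable(values=values, sample_groups=groups)


def simulate_enhancers(
    config: SimulationConfig,
    annotation: Sequence[TranscriptAnnotation],
    layout: GenomeLayout,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[dict[str, PeakSet], pd.DataFrame]:
    """Intergenic K27ac peaks realizing the configured activity patterns.

    Elements are placed clear of gene spans (clearance covers promoter K4me3
    peaks plus their 1-kb extension) and >= enhancer_spacing apart, so the
    enhancer caller recovers each planted element and its pattern exactly at
    zero noise. Returns per-cell-type K27ac PeakSets and the truth table.
    """
    patterns = [
        p for p, cnt in config.enhancer_counts.items() for _ in range(cnt)
    ]
    rng.shuffle(patterns)
    # free gaps between clearance-padded gene spans
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in layout}
    for tx in annotation:
        occupied[tx.chrom].append(
            (max(0, tx.tx_start - config.enhancer_clearance),
             min(layout[tx.chrom], tx.tx_end + config.enhancer_clearance))
        )
    gaps: list[tuple[str, int, int]] = []
    for chrom, spans in occupied.items():
        spans.sort()
        cursor = 0
        for s, e in spans + [(layout[chrom], layout[chrom])]:
            if s - cursor >= config.enhancer_spacing:
                gaps.append((chrom, cursor, s))
            cursor = max(cursor, e)
    order = rng.permutation(len(gaps))
    lo, hi = config.enhancer_length_range
    placed: list[tuple[str, int, int, str]] = []
    idx = 0
    for gi in order:
        chrom, gstart, gend = gaps[gi]
        cursor = gstart
        while idx < len(patterns):
            length = int(rng.integers(lo, hi + 1))
            jitter = int(rng.integers(0, config.enhancer_spacing))
            start = cursor + jitter
            if start + length + config.enhancer_spacing > gend:
                break
            placed.append((chrom, start, start + length, patterns[idx]))
            idx += 1
            cursor = start + length + config.enhancer_spacing
        if idx == len(patterns):
            break
    if idx < len(patterns):
        raise ValueError(
            f"could not place all enhancers ({idx}/{len(patterns)} placed); "
            "genome too crowded for the requested design"
        )
    placed.sort()
    by_gene = {tx.gene_id: tx for tx in annotation}
    rows = []
    k27ac: dict[str, list[GenomicInterval]] = {ct: [] for ct in config.cell_types}
    for i, (chrom, start, end, pattern) in enumerate(placed):
        nearest, best = "", None
        for tx in annotation:
            if tx.chrom != chrom:
                continue
            if end > tx.tx_start and start < tx.tx_end:
                d = 0
            else:
                d = min(abs(tx.tx_start - end), abs(start - tx.tx_start),
                        abs(tx.tx_end - end), abs(start - tx.tx_end))
            if d <= 100_000 and (best is None or d < best):
                nearest, best = tx.gene_id, d
        rows.append(
            {"chrom": chrom, "start": start, "end": end,
             "pattern": pattern, "linked_gene": nearest}
        )
        for ct in config.cell_types:
            if ct[0].upper() in pattern:
                if config.enhancer_fn and rng.random() < config.enhancer_fn:
                    continue
                k27ac[ct].append(
                    GenomicInterval(chrom, start, end, score=PEAK_SCORE)
                )
    peak_sets = {
        ct: PeakSet(f"{ct}_K27ac", ct, "K27ac", ivs) for ct, ivs in k27ac.items()
    }
    enhancer_truth = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "pattern", "linked_gene"]
    )
    truth.enhancers = enhancer_truth
    return peak_sets, enhancer_truth


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run every generator stage under one seed; fully deterministic."""
    seq = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in seq.spawn(4)]
    layout, annotation = simulate_annotation(config, rngs[0])
    coverage, peaks, truth = simulate_chromatin(config, annotation, layout, rngs[1])
    expression = simulate_expression(config, truth, rngs[2])
    k27ac, _ = simulate_enhancers(config, annotation, layout, truth, rngs[3])
    return SyntheticStudy(
        config=config,
        layout=layout,
        annotation=annotation,
        chip_peaks=peaks,
        coverage=coverage,
        k27ac_peaks=k27ac,
        expression=expression,
        truth=truth,
    )
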