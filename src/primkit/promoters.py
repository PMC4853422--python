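"""Promoter definition, chromatin-state coding, replicate consensus, and PRIM.

A promoter is the window TSS +/- flank (default 2 kb) of a gene's canonical
transcript. Each (gene, sample) pair receives a state code from overlap with
that sample's K4me3 and K27me3 peaks:

    1   K4me3 only
    0   K4me3 + K27me3 (bivalent)
   -1   K27me3 only
    NA  no modification

PRIM, the promoter read-intensity ratio for histone modification, is

    PRIM = log2((K4me3 + a) / (K27me3 + a)),   a = 0.001,

with K4me3/K27me3 the reads-per-million-scaled mean depth over the promoter.
PRIM is evaluated only at promoters with a detectable K4me3 or K27me3 peak
(state != NA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    CoverageTrack,
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    TranscriptAnnotation,
    build_interval_index,
    any_overlap,
)

DEFAULT_FLANK = 2000
DEFAULT_PSEUDOCOUNT = 0.001

STATE_K4_ONLY = 1
STATE_BIVALENT = 0
STATE_K27_ONLY = -1
STATE_DTYPE = "Int8"


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    interval: GenomicInterval
    tss: int
    strand: str


class PromoterSet(dict):
    """Mapping gene id -> Promoter; one canonical promoter per gene."""

    @property
    def genes(self) -> list[str]:
        return list(self)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.values()]


def define_promoters(
    annotation: Sequence[TranscriptAnnotation],
    flank: int = DEFAULT_FLANK,
    layout: GenomeLayout | None = None,
) -> PromoterSet:
    """One promoter [TSS-flank, TSS+flank) per gene, clamped to the genome.

    The canonical transcript is the longest; ties break to the lowest
    txStart, then lexicographically smallest transcript id.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    by_gene: dict[str, TranscriptAnnotation] = {}
    for tx in annotation:
        cur = by_gene.get(tx.gene_id)
        key = (-(tx.tx_end - tx.tx_start), tx.tx_start, tx.transcript_id)
        if cur is None or key < (
            -(cur.tx_end - cur.tx_start), cur.tx_start, cur.transcript_id,
        ):
            by_gene[tx.gene_id] = tx
    promoters = PromoterSet()
    for gene_id in sorted(by_gene):
        tx = by_gene[gene_id]
        start = max(0, tx.tss - flank)
        end = tx.tss + flank
        if layout is not None:
            if tx.chrom not in layout:
                warnings.warn(f"gene {gene_id}: unknown chromosome, omitted")
                continue
            end = min(end, layout[tx.chrom])
        promoters[gene_id] = Promoter(
            gene_id, GenomicInterval(tx.chrom, start, end, tx.strand), tx.tss, tx.strand
        )
    return promoters


def call_promoter_state(
    promoters: PromoterSet, k4_peaks: PeakSet, k27_peaks: PeakSet
) -> pd.Series:
    """State code per gene from one sample's K4me3 and K27me3 peaks.

    Overlap means >= 1 shared base. Returns a nullable Int8 Series indexed
    by gene; NA where neither mark overlaps the promoter.
    """
    ivs = promoters.intervals()
    has_k4 = any_overlap(ivs, build_interval_index(k4_peaks))
    has_k27 = any_overlap(ivs, build_interval_index(k27_peaks))
    codes = np.select(
        [has_k4 & ~has_k27, has_k4 & has_k27, ~has_k4 & has_k27],
        [STATE_K4_ONLY, STATE_BIVALENT, STATE_K27_ONLY],
        default=0,
    )
    out = pd.Series(codes, index=pd.Index(promoters.genes, name="gene"), dtype=STATE_DTYPE)
    out[~has_k4 & ~has_k27] = pd.NA
    return out


def consensus_bivalent_genes(
    state_columns: Sequence[pd.Series], min_support: int = 2
) -> set[str]:
    """Genes bivalent (state 0) in at least `min_support` replicates."""
    if len(state_columns) < min_support:
        raise ValueError(
            f"need >= {min_support} replicate columns, got {len(state_columns)}"
        )
    counts = sum(
        (col == STATE_BIVALENT).fillna(False).astype(int) for col in state_columns
    )
    return set(counts.index[counts >= min_support])


def consensus_state(
    state_columns: Sequence[pd.Series], min_support: int = 2
) -> pd.Series:
    """Cell-type-level state from replicate state columns.

    A mark counts as present at a promoter when it is seen (through the
    state code) in at least `min_support` replicates; the consensus state
    is then re-coded from the two mark-presence calls. With min_support=2
    this reduces to the "at least two biological repeats" bivalency rule
    for the bivalent code.
    """
    if len(state_columns) < min_support:
        raise ValueError(
            f"need >= {min_support} replicate columns, got {len(state_columns)}"
        )
    k4_votes = sum(
        col.isin([STATE_K4_ONLY, STATE_BIVALENT]).fillna(False).astype(int)
        for col in state_columns
    )
    k27_votes = sum(
        col.isin([STATE_BIVALENT, STATE_K27_ONLY]).fillna(False).astype(int)
        for col in state_columns
    )
    has_k4 = (k4_votes >= min_support).to_numpy()
    has_k27 = (k27_votes >= min_support).to_numpy()
    codes = np.select(
        [has_k4 & ~has_k27, has_k4 & has_k27, ~has_k4 & has_k27],
        [STATE_K4_ONLY, STATE_BIVALENT, STATE_K27_ONLY],
        default=0,
    )
    out = pd.Series(codes, index=state_columns[0].index, dtype=STATE_DTYPE)
    out[~has_k4 & ~has_k27] = pd.NA
    return out


def mean_promoter_signal(coverage: CoverageTrack, promoter: Promoter) -> float:
    """Reads-per-million-scaled mean depth over the promoter window."""
    iv = promoter.interval
    if iv.chrom not in coverage.chroms:
        raise KeyError(
            f"promoter chromosome {iv.chrom} absent from track {coverage.sample_id}"
        )
    raw = coverage.mean_depth(iv.chrom, iv.start, iv.end)
    return raw * 1e6 / coverage.library_size


def promoter_signal_column(
    coverage: CoverageTrack, promoters: PromoterSet
) -> pd.Series:
    """mean_promoter_signal for every gene, as a Series."""
    vals = [mean_promoter_signal(coverage, p) for p in promoters.values()]
    return pd.Series(vals, index=pd.Index(promoters.genes, name="gene"), dtype=float)


def compute_prim(k4_signal, k27_signal, a: float = DEFAULT_PSEUDOCOUNT):
    """log2((K4me3 + a) / (K27me3 + a)); finite for all non-negative inputs."""
    k4 = np.asarray(k4_signal, dtype=float)
    k27 = np.asarray(k27_signal, dtype=float)
    if a <= 0:
        raise ValueError("pseudocount a must be positive")
    if np.any(k4 < 0) or np.any(k27 < 0):
        raise ValueError("signals must be non-negative")
    out = np.log2(k4 + a) - np.log2(k27 + a)
    if np.isscalar(k4_signal) and np.isscalar(k27_signal):
        return float(out)
    return out


def build_prim_table(
    states: pd.DataFrame,
    k4_signals: pd.DataFrame,
    k27_signals: pd.DataFrame,
    a: float = DEFAULT_PSEUDOCOUNT,
    sample_groups: Mapping[str, str] | None = None,
    min_support: int = 2,
) -> pd.DataFrame:
    """PRIM per (gene, sample), or per (gene, cell type) when grouped.

    All three frames must share the same gene index and sample columns.
    When `sample_groups` maps samples to cell types, replicate signals are
    averaged per mark before the ratio and the cell-type state comes from
    `consensus_state`; PRIM is defined exactly where state != NA.
    """
    if not (
        states.index.equals(k4_signals.index)
        and states.index.equals(k27_signals.index)
        and list(states.columns) == list(k4_signals.columns) == list(k27_signals.columns)
    ):
        raise ValueError("states and signal tables must share an identical grid")
    if sample_groups is not None:
        missing = set(states.columns) - set(sample_groups)
        if missing:
            raise ValueError(f"samples missing from group map: {sorted(missing)}")
        cell_types = list(dict.fromkeys(sample_groups[s] for s in states.columns))
        prim = {}
        for ct in cell_types:
            cols = [s for s in states.columns if sample_groups[s] == ct]
            support = min(min_support, len(cols))
            ct_state = consensus_state([states[c] for c in cols], support)
            k4 = k4_signals[cols].mean(axis=1)
            k27 = k27_signals[cols].mean(axis=1)
            vals = compute_prim(k4.to_numpy(), k27.to_numpy(), a)
            col = pd.Series(vals, index=states.index, dtype=float)
            col[ct_state.isna()] = np.nan
            prim[ct] = col
        return pd.DataFrame(prim)
    vals = compute_prim(k4_signals.to_numpy(), k27_signals.to_numpy(), a)
    out = pd.DataFrame(vals, index=states.index, columns=states.columns)
    out[states.isna()] = np.nan
    return out
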