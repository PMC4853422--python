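"""Rule-based enhancer calling and cross-cell-type activity partitioning.

An enhancer is an intergenic K27ac+/K4me3- element: per cell type, that cell
type's K4me3 peaks are extended 1 kb each way; K27ac peaks overlapping an
extended K4me3 peak, any gene body, or any TSS/TES position are discarded;
the survivors are merged when separated by <= 500 bp. The per-cell-type
enhancer sets are then pooled across cell types and merged again into one
catalog of disjoint elements. An element is active in a cell type when it
overlaps (>= 1 base) that cell type's K27ac peaks, giving the seven-way
S/M/E/SM/SE/ME/SME partition over SSC, MASC and ESC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    TranscriptAnnotation,
    any_overlap,
    build_interval_index,
    extend_intervals,
    merge_intervals,
)

DEFAULT_K4_EXTENSION = 1000
DEFAULT_MERGE_GAP = 500
DEFAULT_WINDOW = 100_000

CELL_TYPES = ("SSC", "MASC", "ESC")
INITIALS = {"SSC": "S", "MASC": "M", "ESC": "E"}
SUBSET_LABELS = ("S", "M", "E", "SM", "SE", "ME", "SME")


@dataclass
class EnhancerCatalog:
    """Disjoint intergenic K27ac elements with per-cell-type annotations.

    ``table`` columns: chrom, start, end, enhancer_id, contributors
    (cell types whose per-cell-type calls produced the element), then after
    assign_activity: active_<ct> flags; after partition_activity: subset;
    after annotate_enhancer_genes: transcripts (list of (transcript_id,
    gene_id, distance)).
    """

    table: pd.DataFrame
    cell_types: tuple[str, ...] = CELL_TYPES

    def __len__(self) -> int:
        return len(self.table)

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in self.table.itertuples()
        ]

    def flag_columns(self) -> list[str]:
        return [f"active_{ct}" for ct in self.cell_types]


def _exclusion_intervals(
    annotation: Sequence[TranscriptAnnotation],
) -> list[GenomicInterval]:
    """Gene bodies plus 1-bp TSS/TES point intervals."""
    out: list[GenomicInterval] = []
    for tx in annotation:
        out.append(GenomicInterval(tx.chrom, tx.tx_start, tx.tx_end))
        # txEnd is exclusive, so the base *at* coordinate txEnd lies outside
        # the body; exclude it as the transcription end point.
        out.append(GenomicInterval(tx.chrom, tx.tx_end, tx.tx_end + 1))
    return out


def call_enhancers(
    k27ac_peaks: Mapping[str, PeakSet],
    k4me3_peaks: Mapping[str, PeakSet],
    annotation: Sequence[TranscriptAnnotation],
    layout: GenomeLayout | None = None,
    k4_extension: int = DEFAULT_K4_EXTENSION,
    merge_gap: int = DEFAULT_MERGE_GAP,
    cell_types: Sequence[str] = CELL_TYPES,
    k4_union: bool = False,
) -> EnhancerCatalog:
    """Two-stage enhancer call: per-cell-type filter+merge, then pooled merge.

    With ``k4_union`` the exclusion uses the union of all cell types' K4me3
    peaks instead of each cell type's own.
    """
    for ct in cell_types:
        if ct not in k27ac_peaks or ct not in k4me3_peaks:
            raise ValueError(f"missing K27ac or K4me3 peaks for cell type {ct}")
    gene_exclusions = _exclusion_intervals(annotation)
    union_k4: list[GenomicInterval] = []
    if k4_union:
        for ct in cell_types:
            union_k4.extend(k4me3_peaks[ct].intervals)
    per_ct: dict[str, list[GenomicInterval]] = {}
    for ct in cell_types:
        k4 = union_k4 if k4_union else k4me3_peaks[ct].intervals
        extended_k4 = extend_intervals(k4, k4_extension, layout)
        exclusion = build_interval_index(list(extended_k4) + gene_exclusions)
        candidates = k27ac_peaks[ct].intervals
        keep = ~any_overlap(candidates, exclusion)
        survivors = [iv for iv, ok in zip(candidates, keep) if ok]
        per_ct[ct] = merge_intervals(survivors, merge_gap)
    pooled = [iv for ct in cell_types for iv in per_ct[ct]]
    catalog_ivs = merge_intervals(pooled, merge_gap)
    per_ct_index = {ct: build_interval_index(per_ct[ct]) for ct in cell_types}
    rows = []
    for i, iv in enumerate(catalog_ivs):
        contributors = [
            ct
            for ct in cell_types
            if any_overlap([iv], per_ct_index[ct])[0]
        ]
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "enhancer_id": f"enh{i + 1:05d}",
                "contributors": ",".join(contributors),
            }
        )
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "enhancer_id", "contributors"]
    )
    return EnhancerCatalog(table=table, cell_types=tuple(cell_types))


def assign_activity(
    catalog: EnhancerCatalog, k27ac_peaks: Mapping[str, PeakSet]
) -> EnhancerCatalog:
    """Flag each element active in a cell type on >= 1-base K27ac overlap.

    Elements active nowhere are removed.
    """
    table = catalog.table.copy()
    ivs = catalog.intervals()
    for ct in catalog.cell_types:
        index = build_interval_index(k27ac_peaks[ct].intervals)
        table[f"active_{ct}"] = any_overlap(ivs, index)
    flags = table[[f"active_{ct}" for ct in catalog.cell_types]]
    table = table.loc[flags.any(axis=1)].reset_index(drop=True)
    return EnhancerCatalog(table=table, cell_types=catalog.cell_types)


def partition_activity(catalog: EnhancerCatalog) -> EnhancerCatalog:
    """Subset label = concatenated initials of active cell types (S, M, E)."""
    table = catalog.table.copy()
    # initials always concatenate in S, M, E order, whatever the input order
    order = [ct for ct in CELL_TYPES if ct in catalog.cell_types] + [
        ct for ct in catalog.cell_types if ct not in CELL_TYPES
    ]
    labels = []
    for _, row in table.iterrows():
        label = "".join(
            INITIALS.get(ct, ct[0].upper())
            for ct in order
            if row[f"active_{ct}"]
        )
        if not label:
            raise ValueError("enhancer with no active cell type in catalog")
        labels.append(label)
    table["subset"] = labels
    return EnhancerCatalog(table=table, cell_types=catalog.cell_types)


def _point_gap(start: int, end: int, point: int) -> int:
    """Bases between [start, end) and a coordinate; 0 when inside/abutting end."""
    if point < start:
        return start - point
    if point > end:
        return point - end
    return 0


def annotate_enhancer_genes(
    catalog: EnhancerCatalog,
    annotation: Sequence[TranscriptAnnotation],
    window: int = DEFAULT_WINDOW,
) -> EnhancerCatalog:
    """Associate every transcript within `window` of either boundary.

    Distance is the minimum gap between the element and the transcript's
    txStart or txEnd (0 when the element overlaps or lies within the
    transcript span).
    """
    by_chrom: dict[str, list[TranscriptAnnotation]] = {}
    for tx in annotation:
        by_chrom.setdefault(tx.chrom, []).append(tx)
    table = catalog.table.copy()
    assoc = []
    for row in table.itertuples():
        hits = []
        for tx in by_chrom.get(row.chrom, []):
            if row.end > tx.tx_start and row.start < tx.tx_end:
                d = 0
            else:
                d = min(
                    _point_gap(row.start, row.end, tx.tx_start),
                    _point_gap(row.start, row.end, tx.tx_end),
                )
            if d <= window:
                hits.append((tx.transcript_id, tx.gene_id, d))
        assoc.append(sorted(hits, key=lambda t: (t[2], t[0])))
    table["transcripts"] = assoc
    return EnhancerCatalog(table=table, cell_types=catalog.cell_types)


def class_association_summary(
    catalog: EnhancerCatalog, classes: pd.Series
) -> pd.DataFrame:
    """Per subset: fraction of elements near class I and class II genes.

    An element is "near" a class when any associated transcript's gene is
    in that class; elements near both count in both. Empty subsets report
    NaN fractions (undefined, not zero).
    """
    class_map = classes.to_dict()
    rows = []
    for label in SUBSET_LABELS:
        sub = catalog.table.loc[catalog.table["subset"] == label]
        n = len(sub)
        if n == 0:
            rows.append({"subset": label, "n": 0,
                         "frac_class_I": np.nan, "frac_class_II": np.nan})
            continue
        near_i = near_ii = 0
        for hits in sub["transcripts"]:
            cls = {class_map.get(gene_id) for _, gene_id, _ in hits}
            near_i += "I" in cls
            near_ii += "II" in cls
        rows.append(
            {
                "subset": label,
                "n": n,
                "frac_class_I": near_i / n,
                "frac_class_II": near_ii / n,
            }
        )
    return pd.DataFrame(rows).set_index("subset")


def count_tf_peaks(
    regions: Sequence[GenomicInterval],
    tf_peak_sets: Mapping[str, Sequence[GenomicInterval]],
    region_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Regions x TF matrix of overlapping peak counts (>= 1 shared base)."""
    if region_ids is None:
        region_ids = [f"region{i + 1}" for i in range(len(regions))]
    counts = {}
    for tf, peaks in tf_peak_sets.items():
        index = build_interval_index(peaks)
        col = np.zeros(len(regions), dtype=int)
        for i, iv in enumerate(regions):
            tree = index.get(iv.chrom)
            if tree is not None:
                col[i] = len(tree.overlap(iv.start, iv.end))
        counts[tf] = col
    return pd.DataFrame(counts, index=pd.Index(region_ids, name="region"))
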