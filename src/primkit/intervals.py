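"""Genomic interval primitives, standard-format readers, and interval algebra.

All coordinates are 0-based half-open internally: BED and bedGraph are native,
GTF (1-based inclusive) is converted on read. Two intervals overlap when they
share at least one base; touching spans such as [0,10) and [10,20) do not
overlap. Files are read gzip-transparently by suffix.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

MARKS = ("K4me3", "K27me3", "K27ac")
STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A malformed record in an input file; the message names the line."""


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.score is not None and self.score < 0:
            raise ValueError(f"negative score {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class GenomeLayout(dict):
    """Mapping chromosome -> length in bases."""

    def __init__(self, lengths: Mapping[str, int]):
        for chrom, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        super().__init__(lengths)

    def validate(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self:
            raise ValueError(f"unknown chromosome {interval.chrom}")
        if interval.end > self[interval.chrom]:
            raise ValueError(
                f"interval {interval.chrom}:[{interval.start},{interval.end}) "
                f"exceeds chromosome length {self[interval.chrom]}"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        out: dict[str, int] = {}
        with _open_text(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, length = line.split()[:2]
                out[chrom] = int(length)
        return cls(out)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.items():
                fh.write(f"{chrom}\t{length}\n")


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


@dataclass
class PeakSet:
    """Peak calls from one sample for one histone mark.

    Peak significance scores (the upstream caller's t / FDR convention) are
    carried opaquely in ``GenomicInterval.score``.
    """

    sample_id: str
    cell_type: str
    mark: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {MARKS}")
        self.intervals = sort_intervals(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript; TSS is txStart on +, txEnd on -."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: invalid strand {self.strand!r}"
            )
        if not self.tx_start < self.tx_end:
            raise ValueError(
                f"transcript {self.transcript_id}: txStart must be < txEnd"
            )

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end, self.strand)


class CoverageTrack:
    """Piecewise-constant read depth for one sample and mark.

    Stored per chromosome as sorted, non-overlapping (start, end, value)
    records; gaps read as depth 0. ``library_size`` is the total mapped
    reads used for reads-per-million normalization.
    """

    def __init__(
        self,
        sample_id: str,
        mark: str,
        records: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        library_size: int,
    ):
        if library_size <= 0:
            raise ValueError("library_size must be positive")
        self.sample_id = sample_id
        self.mark = mark
        self.library_size = int(library_size)
        self._chroms: dict[str, dict[str, np.ndarray]] = {}
        for chrom, (starts, ends, values) in records.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(values < 0):
                raise ValueError(f"negative coverage value on {chrom}")
            if np.any(ends <= starts):
                raise ValueError(f"empty coverage record on {chrom}")
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping coverage records on {chrom}")
            # cumulative integral of depth up to the end of each record
            widths = (ends - starts).astype(np.float64)
            cum = np.cumsum(values * widths)
            self._chroms[chrom] = {
                "starts": starts,
                "ends": ends,
                "values": values,
                "cum": cum,
            }

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._chroms)

    def _integral(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of depth over [0, pos) for an array of positions."""
        rec = self._chroms[chrom]
        starts, ends, values, cum = (
            rec["starts"], rec["ends"], rec["values"], rec["cum"],
        )
        pos = np.asarray(pos, dtype=np.int64)
        idx = np.searchsorted(starts, pos, side="right") - 1
        idx_c = np.clip(idx, 0, None)
        base = np.where(idx > 0, cum[np.clip(idx - 1, 0, None)], 0.0)
        inside = np.clip(pos - starts[idx_c], 0, ends[idx_c] - starts[idx_c])
        extra = values[idx_c] * inside
        return np.where(idx < 0, 0.0, base + extra)

    def depth_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._chroms:
            raise KeyError(f"chromosome {chrom} absent from track")
        rec = self._chroms[chrom]
        idx = int(np.searchsorted(rec["starts"], pos, side="right")) - 1
        if idx < 0 or pos >= rec["ends"][idx]:
            return 0.0
        return float(rec["values"][idx])

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        """Raw mean per-base depth over [start, end); gaps count as 0."""
        if chrom not in self._chroms:
            raise KeyError(f"chromosome {chrom} absent from track")
        if not start < end:
            raise ValueError("require start < end")
        start = max(start, 0)
        lo, hi = self._integral(chrom, np.array([start, end]))
        return float(hi - lo) / (end - start)

    def binned_means(
        self, chrom: str, start: int, end: int, bin_width: int
    ) -> np.ndarray:
        """Raw mean depth in consecutive bins tiling [start, end).

        Bins extending past the chromosome origin read as depth 0 over the
        missing bases; each bin is divided by the full bin width.
        """
        if (end - start) % bin_width:
            raise ValueError("bin_width must divide the window length")
        if chrom not in self._chroms:
            raise KeyError(f"chromosome {chrom} absent from track")
        edges = np.arange(start, end + bin_width, bin_width)
        integ = self._integral(chrom, np.clip(edges, 0, None))
        return np.diff(integ) / bin_width


def parse_bed(
    path: str | Path,
    mark: str = "K4me3",
    sample_id: str = "",
    cell_type: str = "",
) -> PeakSet:
    """Read a 3+-column BED file of peaks into a sorted PeakSet.

    Column 5 (0-based index 4), when present, is stored as the peak score.
    """
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path} line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from exc
            score = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path} line {lineno}: bad score") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, score))
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
    return PeakSet(sample_id, cell_type, mark, intervals)


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals as BED3/BED6 (BED6 when names are given)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = scores[i] if scores is not None else (iv.score or 0)
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t"
                    f"{score:g}\t{iv.strand}\n"
                )


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def parse_annotation(
    path: str | Path,
    dialect: str = "refflat",
    layout: GenomeLayout | None = None,
) -> list[TranscriptAnnotation]:
    """Read transcript models from GTF or a refFlat-like TSV.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    The refFlat dialect expects at least 6 tab-separated columns:
    gene, transcript, chrom, strand, txStart, txEnd (already 0-based
    half-open, as in UCSC refFlat).
    """
    dialect = dialect.lower()
    if dialect not in ("gtf", "refflat"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    transcripts: list[TranscriptAnnotation] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "gtf":
                    if len(fields) < 9 or fields[2] != "transcript":
                        continue
                    attrs = _parse_gtf_attributes(fields[8])
                    tx = TranscriptAnnotation(
                        transcript_id=attrs.get("transcript_id", f"tx{lineno}"),
                        gene_id=attrs.get("gene_id", f"gene{lineno}"),
                        chrom=fields[0],
                        strand=fields[6],
                        tx_start=int(fields[3]) - 1,
                        tx_end=int(fields[4]),
                    )
                else:
                    if len(fields) < 6:
                        raise ParseError(
                            f"{path} line {lineno}: fewer than 6 columns"
                        )
                    tx = TranscriptAnnotation(
                        transcript_id=fields[1],
                        gene_id=fields[0],
                        chrom=fields[2],
                        strand=fields[3],
                        tx_start=int(fields[4]),
                        tx_end=int(fields[5]),
                    )
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
            if layout is not None:
                if tx.chrom not in layout:
                    raise ParseError(
                        f"{path} line {lineno}: unknown chromosome {tx.chrom}"
                    )
                layout.validate(tx.span)
            transcripts.append(tx)
    return transcripts


def write_annotation(
    transcripts: Sequence[TranscriptAnnotation], path: str | Path
) -> None:
    """Write transcripts in the refFlat-like TSV dialect."""
    with open(path, "w") as fh:
        for tx in transcripts:
            fh.write(
                f"{tx.gene_id}\t{tx.transcript_id}\t{tx.chrom}\t{tx.strand}\t"
                f"{tx.tx_start}\t{tx.tx_end}\n"
            )


def load_coverage(
    path: str | Path, sample_id: str, mark: str, library_size: int
) -> CoverageTrack:
    """Read a bedGraph (chrom, start, end, value) into a CoverageTrack.

    Records must be non-overlapping and non-negative; gaps read as depth 0.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    if (frame["value"] < 0).any():
        raise ParseError(f"{path}: negative coverage value")
    records: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in frame.groupby("chrom", sort=True):
        records[str(chrom)] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["value"].to_numpy(),
        )
    try:
        return CoverageTrack(sample_id, mark, records, library_size)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    frames = []
    for chrom in track.chroms:
        rec = track._chroms[chrom]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": rec["starts"],
                    "end": rec["ends"],
                    "value": rec["values"],
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", header=False, index=False)


def extend_intervals(
    intervals: Iterable[GenomicInterval],
    flank: int,
    layout: GenomeLayout | None = None,
) -> list[GenomicInterval]:
    """Extend each interval by `flank` bases each way, clamped to the genome.

    Output is re-sorted but NOT merged.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for iv in intervals:
        start = max(0, iv.start - flank)
        end = iv.end + flank
        if layout is not None and iv.chrom in layout:
            end = min(end, layout[iv.chrom])
        out.append(GenomicInterval(iv.chrom, start, end, iv.strand, iv.score))
    return sort_intervals(out)


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge same-chromosome intervals separated by <= `gap` bases.

    Separation is edge-to-edge (next.start - prev.end); touching or
    overlapping intervals are always merged. Idempotent and
    order-independent. Strand and score are dropped on merge.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= gap
        ):
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    iv.chrom, merged[-1].start, iv.end
                )
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def build_interval_index(
    intervals: Iterable[GenomicInterval],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    # payload carries a unique ordinal so duplicate spans are all retained
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (i, iv))
    return trees


def overlap_query(
    intervals_a: Sequence[GenomicInterval],
    intervals_b: Sequence[GenomicInterval],
) -> list[list[GenomicInterval]]:
    """For each a-interval, the b-intervals sharing >= 1 base with it.

    Returned list is parallel to ``intervals_a``; hits are sorted.
    """
    trees = build_interval_index(intervals_b)
    out: list[list[GenomicInterval]] = []
    for iv in intervals_a:
        tree = trees.get(iv.chrom)
        if tree is None:
            out.append([])
        else:
            out.append(
                sort_intervals(hit.data[1] for hit in tree.overlap(iv.start, iv.end))
            )
    return out


def any_overlap(
    intervals: Sequence[GenomicInterval],
    index: dict[str, IntervalTree],
) -> np.ndarray:
    """Boolean mask: does each interval overlap anything in the index?"""
    mask = np.zeros(len(intervals), dtype=bool)
    for i, iv in enumerate(intervals):
        tree = index.get(iv.chrom)
        mask[i] = bool(tree is not None and tree.overlap(iv.start, iv.end))
    return mask
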