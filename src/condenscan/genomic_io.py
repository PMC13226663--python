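"""Readers, writers, and validated containers for the genomic text formats.

All coordinates are 0-based half-open (BED convention) everywhere in the
package. Interval sets are sorted and merged on construction so that every
downstream overlap/classification routine can assume disjoint, ordered loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "CoverageTrack",
    "GeneModel",
    "CountMatrix",
    "read_intervals",
    "write_intervals",
    "read_track",
    "read_counts",
    "write_counts",
    "read_chrom_sizes",
]


class FormatError(ValueError):
    """A malformed record in an input file (reports the offending line)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally named/scored/stranded."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """An ordered, disjoint collection of intervals (merged on construction).

    Overlapping or bookended-identical inputs on the same chromosome are
    merged; merged intervals lose their individual names/scores (a merged
    region is a new locus, not any one of its parts).
    """

    def __init__(
        self, intervals: Iterable[GenomicInterval], source_label: str = ""
    ) -> None:
        self.source_label = source_label
        self.intervals: List[GenomicInterval] = _sort_and_merge(list(intervals))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet({self.source_label!r}, n={len(self)})"

    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def by_chrom(self) -> Dict[str, List[GenomicInterval]]:
        out: Dict[str, List[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


def _sort_and_merge(intervals: List[GenomicInterval]) -> List[GenomicInterval]:
    intervals = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: List[GenomicInterval] = []
    for iv in intervals:
        # overlapping or bookended runs collapse (bedtools-merge behaviour)
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(
                    prev.chrom, prev.start, iv.end, name=None, score=None
                )
        else:
            merged.append(iv)
    return merged


@dataclass
class CoverageTrack:
    """Uniformly binned, non-negative signal per chromosome.

    ``values[chrom][i]`` covers bases ``[i*bin_size, (i+1)*bin_size)``;
    ``total_counts`` is the library depth used for CPM normalization.
    """

    bin_size: int
    values: Dict[str, np.ndarray]
    total_counts: float

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"values for {chrom} must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"negative coverage on {chrom}")
            self.values[chrom] = arr
        if self.total_counts < 0:
            raise ValueError("total_counts must be non-negative")

    def chrom_length(self, chrom: str) -> int:
        # bins cover the chromosome; length is only known up to bin granularity
        return len(self.values[chrom]) * self.bin_size

    def integral(self) -> float:
        """Length-weighted integral of the signal (value * bp summed)."""
        return float(
            sum(arr.sum() for arr in self.values.values()) * self.bin_size
        )

    def scaled(self, factor: float) -> "CoverageTrack":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return CoverageTrack(
            self.bin_size,
            {c: v * factor for c, v in self.values.items()},
            self.total_counts * factor,
        )


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene annotation: TSS plus gene body, strand-aware."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        if not (self.body.start <= self.tss < self.body.end):
            raise ValueError(f"tss of {self.gene_id} outside gene body")
        if self.chrom != self.body.chrom:
            raise ValueError("gene chrom disagrees with body chrom")

    def promoter(self, tss_window: int = 2000) -> GenomicInterval:
        start = max(0, self.tss - tss_window)
        return GenomicInterval(self.chrom, start, self.tss + tss_window)


class CountMatrix:
    """Gene x sample matrix of non-negative integer counts."""

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts: np.ndarray,
        condition_labels: Optional[Sequence[str]] = None,
    ) -> None:
        counts = np.asarray(counts)
        if counts.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError("counts shape does not match gene/sample ids")
        if np.any(counts < 0):
            raise ValueError("negative counts")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        self.counts = counts.astype(np.int64)
        if condition_labels is None:
            condition_labels = ["" for _ in sample_ids]
        if len(condition_labels) != len(sample_ids):
            raise ValueError("one condition label per sample required")
        self.condition_labels = list(condition_labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    def samples_for(self, condition: str) -> List[int]:
        return [
            i for i, lab in enumerate(self.condition_labels) if lab == condition
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.sample_ids
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> Dict[str, int]:
    """Read a 2-column chrom.sizes file into an ordered dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    sizes = {}
    for chrom, size in zip(df["chrom"], df["size"]):
        if int(size) <= 0:
            raise FormatError(f"non-positive size for {chrom}")
        sizes[str(chrom)] = int(size)
    return sizes


def read_intervals(path, source_label: str = "") -> PeakSet:
    """Read BED3/BED6 into a sorted, merged :class:`PeakSet`.

    Coordinates are interpreted 0-based half-open. Malformed lines raise
    :class:`FormatError` naming the line number.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric score"
                    ) from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name, score, strand)
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return PeakSet(intervals, source_label=source_label or str(path))


def write_intervals(peaks: PeakSet, path) -> None:
    """Write a PeakSet as BED (BED6 when names/scores/strands are present)."""
    use_six = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in peaks
    )
    with open(path, "w") as fh:
        for iv in peaks:
            if use_six:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{iv.name if iv.name is not None else '.'}\t"
                    f"{iv.score if iv.score is not None else '.'}\t"
                    f"{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_track(
    path,
    bin_size: int,
    chrom_sizes: Mapping[str, int],
    total_counts: Optional[float] = None,
) -> CoverageTrack:
    """Read a bedGraph onto uniform bins by length-weighted averaging.

    Uncovered bases contribute 0, so the length-weighted integral of the
    signal is conserved exactly. Records must be non-overlapping and must not
    extend past the chromosome end.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    arrays: Dict[str, np.ndarray] = {
        chrom: np.zeros(math.ceil(size / bin_size))
        for chrom, size in chrom_sizes.items()
    }
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in chrom_sizes:
            raise FormatError(f"{path}: unknown chromosome {chrom}")
        size = chrom_sizes[chrom]
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        vals = sub["value"].to_numpy(dtype=float)
        if np.any(starts < 0) or np.any(starts >= ends):
            raise FormatError(f"{path}: invalid record coordinates on {chrom}")
        if np.any(ends > size):
            raise FormatError(
                f"{path}: record beyond end of {chrom} ({size} bp)"
            )
        if np.any(starts[1:] < ends[:-1]):
            raise FormatError(f"{path}: overlapping records on {chrom}")
        arr = arrays[chrom]
        _accumulate(arr, starts, ends, vals, bin_size)
    if total_counts is None:
        total_counts = float(
            sum(a.sum() for a in arrays.values()) * bin_size
        )
    return CoverageTrack(bin_size, arrays, total_counts)


def _accumulate(arr, starts, ends, vals, bin_size) -> None:
    """Add value*overlap mass into bins, then normalize to per-bin means."""
    for s, e, v in zip(starts, ends, vals):
        b0, b1 = s // bin_size, (e - 1) // bin_size
        if b0 == b1:
            arr[b0] += v * (e - s) / bin_size
            continue
        arr[b0] += v * ((b0 + 1) * bin_size - s) / bin_size
        arr[b1] += v * (e - b1 * bin_size) / bin_size
        if b1 - b0 > 1:
            arr[b0 + 1 : b1] += v


def write_track(track: CoverageTrack, path) -> None:
    """Write a track as bedGraph (one record per non-zero run of bins)."""
    with open(path, "w") as fh:
        for chrom, arr in track.values.items():
            for i, v in enumerate(arr):
                if v != 0:
                    s = i * track.bin_size
                    fh.write(f"{chrom}\t{s}\t{s + track.bin_size}\t{v:g}\n")


def read_counts(
    path, condition_labels: Optional[Sequence[str]] = None
) -> CountMatrix:
    """Read a TSV count table (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric cells in count table")
    if np.any(values < 0):
        raise FormatError(f"{path}: negative counts")
    if not np.allclose(values, np.round(values)):
        raise FormatError(f"{path}: non-integer counts")
    return CountMatrix(
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
        values.astype(np.int64),
        condition_labels=condition_labels,
    )


def write_counts(matrix: CountMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_genes(path) -> List[GeneModel]:
    """Read a TSV gene table: gene_id, chrom, strand, tss, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "strand", "tss", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                str(row.gene_id),
                row.chrom,
                row.strand,
                int(row.tss),
                GenomicInterval(row.chrom, int(row.start), int(row.end)),
            )
        )
    return genes


def write_genes(genes: Sequence[GeneModel], path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss,
            "start": g.body.start,
            "end": g.body.end,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
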