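"""Genomic interval data model and interval algebra.

All coordinates are 0-based half-open (BED convention).  Book-ended
intervals do not overlap and are not merged: two intervals overlap iff
they share at least one base pair.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "ChromSizes",
    "RegionSet",
    "GeneModel",
    "SampleInfo",
    "RegionCountMatrix",
    "merge",
    "overlaps",
    "count_reads",
]


class ValidationError(ValueError):
    """Raised when an interval or region set violates its invariants."""


@dataclass
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named chromosome.

    ``summit``, when present, is an absolute coordinate satisfying
    ``start <= summit < end``.  ``score`` is free-form (commonly a
    -log10 p-value or a fold change).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: Optional[float] = None
    summit: Optional[int] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"summit {self.summit} outside [{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.name or "")


class ChromSizes:
    """Mapping of chromosome name to length in bp."""

    def __init__(self, sizes: Mapping[str, int]):
        for chrom, length in sizes.items():
            if length <= 0:
                raise ValidationError(f"chromosome {chrom} has length {length} <= 0")
        self._sizes: Dict[str, int] = dict(sizes)

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ChromSizes) and self._sizes == other._sizes

    def items(self):
        return self._sizes.items()

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self._sizes:
            raise ValidationError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self._sizes[iv.chrom]:
            raise ValidationError(
                f"interval end {iv.end} exceeds {iv.chrom} length "
                f"{self._sizes[iv.chrom]}"
            )


class RegionSet:
    """An ordered collection of intervals, kept sorted by
    (chrom, start, end, name)."""

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        name: str = "",
        genome: Optional[ChromSizes] = None,
    ):
        self.name = name
        self.genome = genome
        self.intervals: List[GenomicInterval] = sorted(
            intervals, key=GenomicInterval.sort_key
        )
        if genome is not None:
            for iv in self.intervals:
                genome.validate(iv)
        self._index: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return [
            (iv.chrom, iv.start, iv.end, iv.strand, iv.score, iv.summit, iv.name)
            for iv in self.intervals
        ] == [
            (iv.chrom, iv.start, iv.end, iv.strand, iv.score, iv.summit, iv.name)
            for iv in other.intervals
        ]

    def add(self, iv: GenomicInterval) -> None:
        if self.genome is not None:
            self.genome.validate(iv)
        keys = [x.sort_key() for x in self.intervals]
        pos = bisect.bisect_left(keys, iv.sort_key())
        self.intervals.insert(pos, iv)
        self._index = None

    def chroms(self) -> List[str]:
        seen: Dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> Dict[str, List[GenomicInterval]]:
        out: Dict[str, List[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def _coord_index(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        # per-chromosome start/end arrays, cached until mutation
        if self._index is None:
            self._index = {
                chrom: (
                    np.array([iv.start for iv in ivs], dtype=np.int64),
                    np.array([iv.end for iv in ivs], dtype=np.int64),
                )
                for chrom, ivs in self.by_chrom().items()
            }
        return self._index

    def total_bp(self) -> int:
        """Total covered base pairs (counting overlaps once)."""
        return sum(iv.length for iv in merge(self))

    def any_overlap(self, iv: GenomicInterval) -> bool:
        """True iff ``iv`` shares >= 1 bp with any interval in the set."""
        idx = self._coord_index().get(iv.chrom)
        if idx is None:
            return False
        starts, ends = idx
        # candidates with start < iv.end; among those need end > iv.start
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        if hi == 0:
            return False
        return bool((ends[:hi] > iv.start).any())


def merge(regions: RegionSet) -> RegionSet:
    """Combine intervals sharing >= 1 bp into maximal disjoint intervals.

    Book-ended intervals are kept separate.  Strand/score/summit/name are
    dropped from merged output.
    """
    merged: List[GenomicInterval] = []
    cur: Optional[List] = None  # [chrom, start, end]
    for iv in regions:
        if cur is not None and iv.chrom == cur[0] and iv.start < cur[2]:
            cur[2] = max(cur[2], iv.end)
        else:
            if cur is not None:
                merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
            cur = [iv.chrom, iv.start, iv.end]
    if cur is not None:
        merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
    return RegionSet(merged, name=regions.name, genome=regions.genome)


def overlaps(a: RegionSet, b: RegionSet) -> Tuple[np.ndarray, float]:
    """Flag each interval of ``a`` that shares >= 1 bp with any interval
    of ``b``; also return the fraction of flagged intervals.

    Raises on mismatched genomes when both sets carry one.
    """
    if a.genome is not None and b.genome is not None and a.genome != b.genome:
        raise ValidationError("region sets have mismatched genomes")
    flags = np.fromiter(
        (b.any_overlap(iv) for iv in a), dtype=bool, count=len(a)
    )
    frac = float(flags.mean()) if len(flags) else float("nan")
    return flags, frac


@dataclass
class GeneModel:
    """Strand-aware gene model.

    ``tss``/``tts`` are boundary coordinates: on the + strand
    ``tss < tts`` and exons live in ``[tss, tts)``; on the - strand
    ``tts < tss`` and exons live in ``[tts, tss)``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValidationError(f"gene {self.gene_id}: require tss < tts on +")
        if self.strand == "-" and not self.tts < self.tss:
            raise ValidationError(f"gene {self.gene_id}: require tts < tss on -")
        lo, hi = min(self.tss, self.tts), max(self.tss, self.tts)
        prev_end = None
        for (s, e) in self.exons:
            if not (lo <= s < e <= hi):
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside gene body"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons overlap or unsorted"
                )
            prev_end = e

    @property
    def span(self) -> Tuple[int, int]:
        return min(self.tss, self.tts), max(self.tss, self.tts)


@dataclass
class SampleInfo:
    sample_id: str
    assay: str = ""
    time_point: str = ""
    replicate: int = 1
    library_size: int = 0


class RegionCountMatrix:
    """Regions x samples raw read counts with per-sample library sizes.

    ``normalized`` scales each column to counts per million mapped reads.
    """

    def __init__(
        self,
        regions: RegionSet,
        samples: Sequence[SampleInfo],
        counts: np.ndarray,
    ):
        counts = np.asarray(counts)
        if counts.shape != (len(regions), len(samples)):
            raise ValidationError(
                f"counts shape {counts.shape} != "
                f"({len(regions)}, {len(samples)})"
            )
        if counts.size and (counts < 0).any():
            raise ValidationError("negative counts")
        if not np.issubdtype(counts.dtype, np.integer):
            if counts.size and not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        for s in samples:
            if s.library_size <= 0:
                raise ValidationError(
                    f"sample {s.sample_id}: library size must be > 0"
                )
        self.regions = regions
        self.samples = list(samples)
        self.counts = counts

    @property
    def library_sizes(self) -> np.ndarray:
        return np.array([s.library_size for s in self.samples], dtype=np.float64)

    @property
    def normalized(self) -> np.ndarray:
        return self.counts / self.library_sizes[None, :] * 1e6

    @property
    def time_points(self) -> List[str]:
        seen: Dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.time_point, None)
        return list(seen)

    def time_labels(self) -> np.ndarray:
        """Integer label per sample, indexing into :meth:`time_points`."""
        tps = {tp: i for i, tp in enumerate(self.time_points)}
        return np.array([tps[s.time_point] for s in self.samples], dtype=np.int64)


def count_reads(
    regions: RegionSet,
    tags: Mapping[str, Sequence[Tuple[str, int]]],
    sample_info: Optional[Mapping[str, SampleInfo]] = None,
) -> RegionCountMatrix:
    """Count 5' read positions falling in each region.

    ``tags`` maps sample_id to a sequence of (chrom, position) read
    positions.  Library size is the total read count of the sample; a
    sample with zero reads is rejected because normalization would be
    undefined.
    """
    sample_ids = list(tags)
    n, s = len(regions), len(sample_ids)
    counts = np.zeros((n, s), dtype=np.int64)
    samples: List[SampleInfo] = []
    for j, sid in enumerate(sample_ids):
        positions = tags[sid]
        if len(positions) == 0:
            raise ValidationError(f"sample {sid} has zero reads")
        by_chrom: Dict[str, List[int]] = {}
        for chrom, pos in positions:
            by_chrom.setdefault(chrom, []).append(pos)
        sorted_pos = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()}
        for i, iv in enumerate(regions):
            arr = sorted_pos.get(iv.chrom)
            if arr is None:
                continue
            lo = np.searchsorted(arr, iv.start, side="left")
            hi = np.searchsorted(arr, iv.end, side="left")
            counts[i, j] = hi - lo
        base = (
            sample_info[sid]
            if sample_info is not None and sid in sample_info
            else SampleInfo(sample_id=sid)
        )
        samples.append(
            SampleInfo(
                sample_id=sid,
                assay=base.assay,
                time_point=base.time_point,
                replicate=base.replicate,
                library_size=len(positions),
            )
        )
    return RegionCountMatrix(regions, samples, counts)
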