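"""Genomic interval algebra.

All coordinates in the package are 0-based half-open (BED convention).
Formats that use other conventions (GTF: 1-based closed; GWAS catalog
positions: 1-based) are converted at the reader boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 base. Strand is ignored."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def __str__(self) -> str:  # genome-browser style, for logs and GraphML
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """>= 1 bp overlap under the half-open convention; strand-blind."""
    return a.overlaps(b)


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge overlapping/neighboring intervals into maximal regions.

    Two intervals end up in the same output region iff a chain of inputs
    connects them with pairwise gaps <= ``max_gap``.  With the default
    ``max_gap=0`` only overlapping or directly abutting (book-ended)
    intervals merge.  Output is sorted and pairwise disjoint per
    chromosome; strand is dropped (merged regions are unstranded).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def clip_interval(
    iv: GenomicInterval, chrom_sizes: Mapping[str, int] | None
) -> GenomicInterval | None:
    """Clip an interval to chromosome bounds; None if nothing remains."""
    if chrom_sizes is None:
        return iv if iv.start >= 0 else replace(iv, start=0)
    size = chrom_sizes.get(iv.chrom)
    if size is None:
        return iv
    start = max(0, iv.start)
    end = min(iv.end, size)
    if end <= start:
        return None
    if (start, end) != (iv.start, iv.end):
        logger.debug("clipped %s to %s:%d-%d", iv, iv.chrom, start, end)
        return GenomicInterval(iv.chrom, start, end, iv.strand)
    return iv


def make_window(
    chrom: str,
    center: int,
    half_width: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> GenomicInterval:
    """Symmetric window [center - half_width, center + half_width), clipped."""
    iv = GenomicInterval(chrom, max(0, center - half_width), center + half_width)
    clipped = clip_interval(iv, chrom_sizes)
    if clipped is None:
        raise ValueError(f"window around {chrom}:{center} falls outside the chromosome")
    return clipped


class CoverageTrack:
    """Piecewise-constant coverage over the genome (bedGraph semantics).

    Per chromosome, intervals are non-overlapping; positions not covered
    by any record have value 0.  ``library_depth`` is the total mapped
    read count used for depth-per-million normalization.
    """

    def __init__(
        self,
        records: Iterable[tuple[str, int, int, float]],
        library_depth: float | None = None,
    ) -> None:
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if end <= start:
                raise ValueError(f"bad coverage interval {chrom}:{start}-{end}")
            if value < 0:
                raise ValueError(f"negative coverage {value} at {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            vals = np.array([r[2] for r in rows], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping coverage intervals on {chrom}")
            self._data[chrom] = (starts, ends, vals)
        self.library_depth = library_depth

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._data)

    def iter_records(self):
        for chrom in sorted(self._data):
            starts, ends, vals = self._data[chrom]
            for s, e, v in zip(starts, ends, vals):
                yield chrom, int(s), int(e), float(v)

    def total_signal(self, interval: GenomicInterval) -> float:
        """Sum of value x covered-length over the interval (unnormalized)."""
        data = self._data.get(interval.chrom)
        if data is None:
            return 0.0
        starts, ends, vals = data
        lo = np.searchsorted(ends, interval.start, side="right")
        hi = np.searchsorted(starts, interval.end, side="left")
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], interval.start)
        e = np.minimum(ends[lo:hi], interval.end)
        return float(np.sum((e - s) * vals[lo:hi]))

    def mean(self, interval: GenomicInterval, per_million: bool = False) -> float:
        """Length-weighted mean over the interval (uncovered bases count 0).

        With ``per_million=True`` the mean is divided by
        ``library_depth / 1e6`` (depth normalization).
        """
        if interval.chrom not in self._data:
            warnings.warn(
                f"chromosome {interval.chrom} absent from coverage track; mean = 0",
                stacklevel=2,
            )
            return 0.0
        value = self.total_signal(interval) / interval.length
        if per_million:
            if not self.library_depth:
                raise ValueError("per_million requested but library_depth is not set")
            value /= self.library_depth / 1e6
        return value


def mean_coverage(
    track: CoverageTrack, interval: GenomicInterval, per_million: bool = False
) -> float:
    """Module-level convenience wrapper around :meth:`CoverageTrack.mean`."""
    return track.mean(interval, per_million=per_million)
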