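"""Genomic interval primitives and set arithmetic.

All coordinates are 0-based, half-open ``[start, end)`` on a named
chromosome. Strand is ``"+"``, ``"-"`` or ``"."`` (strandless). These are
the in-memory substrate for every feature in the package; GFF3's 1-based
inclusive convention is converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", strand_aware: bool = False) -> bool:
        return self.overlap_bp(other, strand_aware=strand_aware) > 0

    def overlap_bp(self, other: "GenomicInterval", strand_aware: bool = False) -> int:
        if self.chrom != other.chrom:
            return 0
        if strand_aware and "." not in (self.strand, other.strand) and self.strand != other.strand:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals on the same chromosome (0 if they
        overlap or abut)."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


def _pairs(intervals: Iterable[GenomicInterval]) -> list[tuple[int, int]]:
    return sorted((iv.start, iv.end) for iv in intervals)


def merge_pairs(pairs: Iterable[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    """Union of ``(start, end)`` pairs, additionally fusing runs separated by
    at most ``gap`` bp."""
    out: list[list[int]] = []
    for s, e in sorted(pairs):
        if out and s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def merge_intervals(
    intervals: Sequence[GenomicInterval], gap: int = 0, strand_aware: bool = False
) -> list[GenomicInterval]:
    """Merge overlapping (or within-``gap``) intervals per chromosome, and per
    strand when ``strand_aware``."""
    groups: dict[tuple, list[GenomicInterval]] = {}
    for iv in intervals:
        key = (iv.chrom, iv.strand) if strand_aware else (iv.chrom,)
        groups.setdefault(key, []).append(iv)
    merged: list[GenomicInterval] = []
    for key in sorted(groups):
        strand = key[1] if strand_aware else "."
        for s, e in merge_pairs(_pairs(groups[key]), gap=gap):
            merged.append(GenomicInterval(key[0], s, e, strand))
    return sorted(merged)


def intersect_pairs(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two pair lists (each assumed disjoint after merge)."""
    a = merge_pairs(a)
    b = merge_pairs(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_pairs(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Bases of ``a`` not covered by ``b``."""
    a = merge_pairs(a)
    b = merge_pairs(b)
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_length(pairs: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_pairs(pairs))


def covered_fraction(
    targets: Sequence[tuple[int, int]], covers: Sequence[tuple[int, int]]
) -> float:
    """Fraction of target bases overlapped by at least one cover interval."""
    denom = total_length(targets)
    if denom == 0:
        raise ValueError("zero target bases")
    return total_length(intersect_pairs(targets, covers)) / denom


class IntervalIndex:
    """Sorted-array overlap index over intervals grouped per chromosome.

    Supports the only two queries the pipeline needs: "any overlap >= min bp"
    and "all intervals overlapping a window". Built once per feature track.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[GenomicInterval]]] = {}
        groups: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            groups.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in groups.items():
            ivs.sort()
            starts = np.array([iv.start for iv in ivs])
            # running max of ends makes the scan early-terminable
            maxend = np.maximum.accumulate(np.array([iv.end for iv in ivs]))
            self._by_chrom[chrom] = (starts, maxend, ivs)

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return []
        starts, maxend, ivs = entry
        hi = int(np.searchsorted(starts, query.end, side="left"))
        out = []
        for k in range(hi - 1, -1, -1):
            if maxend[k] <= query.start:
                break
            if ivs[k].end > query.start:
                out.append(ivs[k])
        out.reverse()
        return out

    def max_overlap_bp(self, query: GenomicInterval, strand_aware: bool = False) -> int:
        return max(
            (query.overlap_bp(iv, strand_aware=strand_aware) for iv in self.overlapping(query)),
            default=0,
        )

    def any_overlap(
        self, query: GenomicInterval, min_bp: int = 1, strand_aware: bool = False
    ) -> bool:
        for iv in self.overlapping(query):
            if query.overlap_bp(iv, strand_aware=strand_aware) >= min_bp:
                return True
        return False
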