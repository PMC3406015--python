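"""Cross-species projection of loci and transcriptional-conservation
classification.

Loci are projected through co-linear syntenic blocks (orthologous position
between genomes; the identity map serves for two taxa annotated on the same
assembly). A locus is called expressed in another species when its
projected position has an overlapping promoter-mark peak (>=1 bp) and at
least one overlapping, strand-matched read; a reads-only mode relaxes the
peak requirement (used when no chromatin data exist for a species).
Conservation categories follow the three-species palette: I all three
rodents, II both mouse taxa only, III focal only, IV sister only, V
outgroup only; loci without an aligned outgroup ortholog are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import (
    GenomicInterval,
    IntervalIndex,
    intersect_pairs,
    merge_pairs,
    total_length,
)

CATEGORIES = ("I", "II", "III", "IV", "V")
_FLIP = {"+": "-", "-": "+", ".": "."}


@dataclass(frozen=True)
class SyntenicBlock:
    """Length-preserving co-linear mapping of a source interval onto a
    target chromosome, optionally strand-flipped."""

    src_chrom: str
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_start: int
    orientation: str = "same"  # same | flipped

    def __post_init__(self) -> None:
        if not (0 <= self.src_start < self.src_end):
            raise ValueError("invalid source interval")
        if self.orientation not in ("same", "flipped"):
            raise ValueError("orientation must be 'same' or 'flipped'")

    @property
    def length(self) -> int:
        return self.src_end - self.src_start


class OrthologyMap:
    """Set of non-overlapping-on-source syntenic blocks."""

    def __init__(self, blocks: Sequence[SyntenicBlock]):
        self.blocks = sorted(blocks, key=lambda b: (b.src_chrom, b.src_start))
        prev: SyntenicBlock | None = None
        for b in self.blocks:
            if prev and prev.src_chrom == b.src_chrom and b.src_start < prev.src_end:
                raise ValueError("overlapping source blocks in orthology map")
            prev = b
        self._by_chrom: dict[str, list[SyntenicBlock]] = {}
        for b in self.blocks:
            self._by_chrom.setdefault(b.src_chrom, []).append(b)

    def invert(self) -> "OrthologyMap":
        inv = []
        for b in self.blocks:
            inv.append(
                SyntenicBlock(
                    b.tgt_chrom,
                    b.tgt_start,
                    b.tgt_start + b.length,
                    b.src_chrom,
                    b.src_start,
                    b.orientation,
                )
            )
        return OrthologyMap(inv)

    @classmethod
    def identity(cls) -> "OrthologyMap":
        return _IdentityMap()


class _IdentityMap(OrthologyMap):
    """Equivalent-position map between two taxa on the same assembly."""

    def __init__(self):  # noqa: D107
        self.blocks = []
        self._by_chrom = {}

    def invert(self) -> "OrthologyMap":
        return self


def project_interval(
    interval: GenomicInterval, orthology_map: OrthologyMap
) -> list[GenomicInterval]:
    """Project an interval through the map.

    Returns the mapped segments (possibly several when the interval spans
    block boundaries; empty when no block overlaps). Flipped blocks
    reverse-complement coordinates and flip the strand.
    """
    if isinstance(orthology_map, _IdentityMap):
        return [interval]
    out = []
    for b in orthology_map._by_chrom.get(interval.chrom, []):
        s = max(interval.start, b.src_start)
        e = min(interval.end, b.src_end)
        if s >= e:
            continue
        if b.orientation == "same":
            ts = b.tgt_start + (s - b.src_start)
            te = b.tgt_start + (e - b.src_start)
            strand = interval.strand
        else:
            ts = b.tgt_start + (b.src_end - e)
            te = b.tgt_start + (b.src_end - s)
            strand = _FLIP[interval.strand]
        out.append(GenomicInterval(b.tgt_chrom, ts, te, strand))
    return out


@dataclass
class SpeciesEvidence:
    species: str
    has_ortholog: bool
    peak_overlap: bool
    read_overlap: bool

    @property
    def expressed_strict(self) -> bool:
        return self.has_ortholog and self.peak_overlap and self.read_overlap

    @property
    def expressed_reads_only(self) -> bool:
        return self.has_ortholog and self.read_overlap


def expression_evidence_at(
    segments: Sequence[GenomicInterval],
    peaks: IntervalIndex | Sequence[GenomicInterval],
    reads: IntervalIndex | Sequence[GenomicInterval],
    species: str = "",
    mode: str = "strict",
    min_overlap_bp: int = 1,
) -> SpeciesEvidence:
    """Evidence of expression at a (projected) region.

    The peak test is strandless; the read test is strand-aware against the
    projected strand (the libraries are stranded). ``segments`` empty means
    no ortholog.
    """
    if mode not in ("strict", "reads_only"):
        raise ValueError("mode must be 'strict' or 'reads_only'")
    if not segments:
        return SpeciesEvidence(species, False, False, False)
    peak_index = peaks if isinstance(peaks, IntervalIndex) else IntervalIndex(list(peaks))
    read_index = reads if isinstance(reads, IntervalIndex) else IntervalIndex(list(reads))
    peak_hit = any(
        peak_index.any_overlap(
            GenomicInterval(seg.chrom, seg.start, seg.end), min_bp=min_overlap_bp
        )
        for seg in segments
    )
    read_hit = any(
        read_index.any_overlap(seg, min_bp=1, strand_aware=True) for seg in segments
    )
    return SpeciesEvidence(species, True, peak_hit, read_hit)


@dataclass
class ConservationCall:
    locus_id: str
    category: str  # I..V or excluded_no_ortholog
    partial_projection: bool = False


def classify_conservation(
    locus_id: str,
    evidence: Sequence[SpeciesEvidence],
    mode: str = "strict",
    partial_projection: bool = False,
) -> ConservationCall:
    """Classify a locus from its (focal, sister, outgroup) evidence vector.

    The outgroup ortholog must be present, else the locus is excluded from
    turnover analysis (sequence turnover, not transcriptional turnover). An
    all-false vector for a locus that carries focal annotation is a
    contradiction and raises; so do vectors outside the five-category
    palette (e.g. focal+outgroup without sister), which the evolutionary
    scenario cannot produce by descent.
    """
    if len(evidence) != 3:
        raise ValueError("need evidence for exactly (focal, sister, outgroup)")
    focal, sister, outgroup = evidence
    if not outgroup.has_ortholog:
        return ConservationCall(locus_id, "excluded_no_ortholog", partial_projection)
    expr = tuple(
        (e.expressed_strict if mode == "strict" else e.expressed_reads_only)
        for e in evidence
    )
    table = {
        (True, True, True): "I",
        (True, True, False): "II",
        (True, False, False): "III",
        (False, True, False): "IV",
        (False, False, True): "V",
    }
    if expr == (False, False, False):
        raise ValueError(
            f"{locus_id}: no expression evidence in any species but the locus "
            "was annotated as expressed"
        )
    if expr not in table:
        raise ValueError(f"{locus_id}: evidence vector {expr} outside the category palette")
    return ConservationCall(locus_id, table[expr], partial_projection)


def exon_coverage_fraction(
    exons: Sequence[GenomicInterval],
    other_species_reads: Sequence[GenomicInterval],
    orthology_map: OrthologyMap,
    strand_aware: bool = True,
) -> tuple[float, bool]:
    """Fraction of projected exonic bases covered by >=1 read in the other
    species. Returns ``(fraction, partial_flag)``; the flag marks exons that
    did not fully project. Raises when nothing projects."""
    projected: list[GenomicInterval] = []
    src_total = sum(iv.length for iv in exons)
    for iv in exons:
        projected.extend(project_interval(iv, orthology_map))
    proj_total = sum(iv.length for iv in projected)
    if proj_total == 0:
        raise ValueError("zero projectable exonic bases")
    covered = 0
    by_key: dict[tuple, list[tuple[int, int]]] = {}
    for seg in projected:
        key = (seg.chrom, seg.strand) if strand_aware else (seg.chrom,)
        by_key.setdefault(key, []).append((seg.start, seg.end))
    read_by_key: dict[tuple, list[tuple[int, int]]] = {}
    for r in other_species_reads:
        key = (r.chrom, r.strand) if strand_aware else (r.chrom,)
        read_by_key.setdefault(key, []).append((r.start, r.end))
    for key, segs in by_key.items():
        reads = read_by_key.get(key, [])
        covered += total_length(intersect_pairs(merge_pairs(segs), reads))
    return covered / proj_total, proj_total < src_total


def turnover_contingency(
    calls_group1: Sequence[ConservationCall],
    calls_group2: Sequence[ConservationCall],
    category: str | Sequence[str],
) -> tuple[list[list[int]], float, tuple[float, float]]:
    """2x2 table (rows = groups, cols = in-category / not), two-tailed
    Fisher exact p, and the in-category proportions per group.

    No-ortholog calls must be excluded by the caller (they are not
    transcriptional turnover).
    """
    cats = {category} if isinstance(category, str) else set(category)
    rows = []
    props = []
    for calls in (calls_group1, calls_group2):
        if not calls:
            raise ValueError("empty call group")
        if any(c.category == "excluded_no_ortholog" for c in calls):
            raise ValueError("no-ortholog calls must be excluded before testing")
        k = sum(1 for c in calls if c.category in cats)
        rows.append([k, len(calls) - k])
        props.append(k / len(calls))
    _, p = stats.fisher_exact(rows, alternative="two-sided")
    return rows, float(p), (props[0], props[1])


def fisher_two_tailed(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher exact p for a printed 2x2 table (sum of
    hypergeometric table probabilities <= that of the observed table)."""
    _, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(p)
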