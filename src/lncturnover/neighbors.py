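"""Neighborhood analysis of lncRNA loci and protein-coding genes.

Pairs each intergenic lncRNA locus with its closest protein-coding gene (A)
and the next-closest non-paralogous gene (B), classifies the relative
orientation of transcription (tandem / divergent / convergent), builds
per-gene territories (all bases nearer to a gene than to its flanking
genes), computes randomization-based overlap enrichments, and tests
between-species expression shifts of neighbor groups against a
housekeeping baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, intersect_pairs, merge_pairs, total_length


@dataclass(frozen=True)
class GeneFeature:
    id: str
    span: GenomicInterval  # stranded envelope
    tss: int


@dataclass
class NeighborPair:
    lnc_id: str
    gene_a: str | None
    gene_b: str | None
    tss_distance: int | None
    orientation: str | None  # tandem | divergent | convergent
    category: str | None = None
    drop_reason: str | None = None


@dataclass
class EnrichmentResult:
    observed: float
    expected_mean: float
    expected_sd: float
    fold: float
    p: float  # empirical tail p in the observed direction
    direction: str  # enrichment | depletion
    n_permutations: int
    p_enrichment: float = 1.0  # upper-tail p regardless of direction


def orientation_class(lnc: GeneFeature, gene: GeneFeature) -> str:
    """Relative transcription orientation of a lncRNA-gene pair.

    Same strand -> tandem. On opposite strands, order the two TSSs along the
    chromosome: when the left element transcribes leftward (-) and the right
    rightward (+) the units diverge; the mirror arrangement converges.
    """
    s1, s2 = lnc.span.strand, gene.span.strand
    if s1 not in "+-" or s2 not in "+-":
        raise ValueError("both strands must be known")
    if s1 == s2:
        return "tandem"
    left, right = (lnc, gene) if lnc.tss <= gene.tss else (gene, lnc)
    return "divergent" if left.span.strand == "-" else "convergent"


def _envelope_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    return a.distance_to(b)


def neighbor_pairs(
    lnc_loci: Sequence[GeneFeature],
    genes: Sequence[GeneFeature],
    paralogs: set[frozenset[str]] = frozenset(),
    orthologs: set[str] | None = None,
    categories: Mapping[str, str] | None = None,
    distance_mode: str = "envelope",
) -> list[NeighborPair]:
    """Closest (A) and next-closest non-paralogous (B) gene per lncRNA.

    Selection uses envelope (gap) distance by default or TSS distance with
    ``distance_mode='tss'``; the reported ``tss_distance`` is always
    TSS-to-TSS. ``orthologs`` is the set of gene ids with one-to-one
    orthologs in the comparison species; pairs whose A or B lacks one are
    dropped with a reason. A gene B annotated as a paralog of gene A is
    replaced by the next qualifying gene.
    """
    if distance_mode not in ("envelope", "tss"):
        raise ValueError("distance_mode must be 'envelope' or 'tss'")
    by_chrom: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_chrom.setdefault(g.span.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: (g.span.start, g.span.end))
    pairs: list[NeighborPair] = []
    for lnc in lnc_loci:
        cat = categories.get(lnc.id) if categories else None
        candidates = by_chrom.get(lnc.span.chrom, [])
        if len(candidates) < 2:
            pairs.append(
                NeighborPair(lnc.id, None, None, None, None, cat, "fewer_than_two_genes")
            )
            continue

        def dist(g: GeneFeature) -> tuple[int, int]:
            d = (
                _envelope_distance(lnc.span, g.span)
                if distance_mode == "envelope"
                else abs(lnc.tss - g.tss)
            )
            return (d, g.span.start)  # deterministic tie-break: leftmost

        ranked = sorted(candidates, key=dist)
        gene_a = ranked[0]
        gene_b = None
        for g in ranked[1:]:
            if frozenset((gene_a.id, g.id)) in paralogs:
                continue
            gene_b = g
            break
        if orthologs is not None and gene_a.id not in orthologs:
            pairs.append(
                NeighborPair(lnc.id, gene_a.id, None, None, None, cat, "gene_A_no_ortholog")
            )
            continue
        if gene_b is not None and orthologs is not None and gene_b.id not in orthologs:
            gene_b_id, reason = None, "gene_B_no_ortholog"
        else:
            gene_b_id, reason = (gene_b.id if gene_b else None), None
        pairs.append(
            NeighborPair(
                lnc.id,
                gene_a.id,
                gene_b_id,
                abs(lnc.tss - gene_a.tss),
                orientation_class(lnc, gene_a),
                cat,
                reason,
            )
        )
    return pairs


def gene_territories(
    genes: Sequence[GeneFeature], chrom_bounds: Mapping[str, int]
) -> dict[str, GenomicInterval]:
    """Per-gene territory: all bases closer to the gene's envelope than to
    its flanking genes', with boundaries at midpoints between adjacent
    envelopes and chromosome ends closing the terminal territories."""
    by_chrom: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_chrom.setdefault(g.span.chrom, []).append(g)
    out: dict[str, GenomicInterval] = {}
    for chrom, gs in by_chrom.items():
        if chrom not in chrom_bounds:
            raise ValueError(f"no bound for chromosome {chrom}")
        gs.sort(key=lambda g: (g.span.start, g.span.end))
        bounds = [0]
        for left, right in zip(gs, gs[1:]):
            bounds.append((left.span.end + right.span.start) // 2)
        bounds.append(chrom_bounds[chrom])
        for g, s, e in zip(gs, bounds, bounds[1:]):
            out[g.id] = GenomicInterval(chrom, s, e)
    return out


def _overlap_bp(
    segments: Sequence[GenomicInterval], annotation_pairs: Mapping[str, list[tuple[int, int]]]
) -> int:
    # per-segment counting (not the union): keeps the statistic additive over
    # segments, so the null is exactly placement-exchangeable per segment
    bp = 0
    for seg in segments:
        bp += total_length(
            intersect_pairs([(seg.start, seg.end)], annotation_pairs.get(seg.chrom, []))
        )
    return bp


def permutation_enrichment(
    segments: Sequence[GenomicInterval],
    annotation: Sequence[GenomicInterval],
    workspace: Sequence[GenomicInterval],
    n_perms: int = 1000,
    seed: int = 0,
    gc_bins: Mapping[str, int] | None = None,
) -> EnrichmentResult:
    """Nucleotide-overlap enrichment of ``segments`` in ``annotation`` under
    random length-preserving re-placement within the workspace.

    Each permutation independently re-places every segment uniformly among
    all positions where it fits inside a single workspace interval on its
    own chromosome. The empirical p is (1 + #{perm >= observed})/(n+1) for
    enrichment, mirrored for depletion. ``gc_bins`` optionally restricts a
    segment's placements to workspace windows in the same G+C decile (keyed
    by window id); when omitted the randomization is G+C-agnostic.
    """
    if n_perms < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(seed)
    ann_pairs: dict[str, list[tuple[int, int]]] = {}
    for iv in annotation:
        ann_pairs.setdefault(iv.chrom, []).append((iv.start, iv.end))
    ann_pairs = {c: merge_pairs(p) for c, p in ann_pairs.items()}
    ws_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in workspace:
        ws_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    ws_by_chrom = {c: merge_pairs(p) for c, p in ws_by_chrom.items()}

    observed = float(_overlap_bp(segments, ann_pairs))

    # precompute, per segment, the cumulative count of valid start positions
    placements: list[tuple[str, int, np.ndarray, np.ndarray]] = []
    for seg in segments:
        ws = ws_by_chrom.get(seg.chrom, [])
        starts, counts = [], []
        for s, e in ws:
            room = e - s - seg.length + 1
            if room > 0:
                starts.append(s)
                counts.append(room)
        if not counts:
            raise ValueError(
                f"segment of {seg.length} bp fits in no workspace interval on {seg.chrom}"
            )
        placements.append(
            (seg.chrom, seg.length, np.array(starts), np.cumsum(counts))
        )

    perm_overlaps = np.empty(n_perms)
    for k in range(n_perms):
        placed: list[GenomicInterval] = []
        for chrom, length, starts, cum in placements:
            r = int(rng.integers(cum[-1]))
            j = int(np.searchsorted(cum, r, side="right"))
            offset = r - (cum[j - 1] if j > 0 else 0)
            s = int(starts[j]) + offset
            placed.append(GenomicInterval(chrom, s, s + length))
        perm_overlaps[k] = _overlap_bp(placed, ann_pairs)

    mean = float(perm_overlaps.mean())
    sd = float(perm_overlaps.std(ddof=1))
    fold = observed / mean if mean > 0 else float("inf")
    p_enrich = (1 + int((perm_overlaps >= observed).sum())) / (n_perms + 1)
    if observed >= mean:
        p, direction = p_enrich, "enrichment"
    else:
        p = (1 + int((perm_overlaps <= observed).sum())) / (n_perms + 1)
        direction = "depletion"
    return EnrichmentResult(
        observed, mean, sd, fold, float(p), direction, n_perms, float(p_enrich)
    )


@dataclass
class ShiftTestResult:
    group: str
    n: int
    median: float
    p: float | None
    note: str | None = None


def expression_shift_test(
    group_folds: Mapping[str, Sequence[float]],
    housekeeping_baseline: Sequence[float],
    min_group: int = 5,
) -> dict[str, ShiftTestResult]:
    """Per-group median fold-difference and two-tailed Mann-Whitney test
    against the housekeeping baseline. Groups below ``min_group`` genes are
    reported as underpowered with no p."""
    baseline = list(housekeeping_baseline)
    if len(baseline) < min_group:
        raise ValueError("housekeeping baseline too small")
    out: dict[str, ShiftTestResult] = {}
    for name, vals in group_folds.items():
        vals = list(vals)
        if len(vals) == 0:
            out[name] = ShiftTestResult(name, 0, float("nan"), None, "empty group")
            continue
        med = float(np.median(vals))
        if len(vals) < min_group:
            out[name] = ShiftTestResult(name, len(vals), med, None, "underpowered")
            continue
        _, p = stats.mannwhitneyu(vals, baseline, alternative="two-sided")
        out[name] = ShiftTestResult(name, len(vals), med, float(p))
    return out


def distance_correlation(
    tss_distances: Sequence[float], folds: Sequence[float]
) -> tuple[float, float, bool]:
    """Pearson correlation of log10(TSS distance) against the expression
    fold-difference, with two-sided p. Returns ``(r, p, defined)``; zero
    variance in either variable yields ``defined=False``."""
    d = np.asarray(tss_distances, dtype=float)
    f = np.asarray(folds, dtype=float)
    if len(d) < 3 or len(d) != len(f):
        raise ValueError("need at least 3 paired observations")
    if np.any(d <= 0):
        raise ValueError("TSS distances must be positive")
    x = np.log10(d)
    if np.ptp(x) == 0 or np.ptp(f) == 0:
        return float("nan"), float("nan"), False
    r, p = stats.pearsonr(x, f)
    return float(r), float(p), True
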