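"""Transcript and promoter annotation.

Turns stranded read intervals (or pre-assembled transfrags) plus H3K4me3
peaks and a protein-coding gene annotation into filtered transcript models,
clustered loci with a class label, 400-bp promoters, antisense calls with
removal reasons, and bidirectional-promoter calls.

The pipeline mirrors a liver transcriptome build: transcripts shorter than
200 nt or without a promoter-mark peak over their predicted TSS are
discarded; intergenic transcripts are screened for coding potential; loci
are transitive clusters of transcripts with overlapping exonic or intronic
bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalIndex, merge_pairs
from .sequences import dinucleotide_shuffle, longest_orf_length


@dataclass(frozen=True)
class TranscriptModel:
    """Stranded exon chain. Exons are sorted, disjoint, same chrom/strand."""

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("transcript strand must be + or -")
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e) or s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        """Most 5' transcribed nucleotide."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class PeakRecord:
    interval: GenomicInterval
    summit: int

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie inside the peak")


@dataclass
class LocusRecord:
    id: str
    interval: GenomicInterval
    members: list[str]
    locus_class: str  # intergenic_lncRNA | protein_coding | intragenic_other


@dataclass
class PromoterRecord:
    transcript_id: str
    interval: GenomicInterval | None
    truncated: bool = False


@dataclass
class AntisenseCall:
    transcript_id: str
    host_gene_id: str
    removal_reason: str  # none | annotated_coding | no_independent_peak | no_5prime_peak | flagged_artifact


def assemble_transfrags(
    reads: Sequence[GenomicInterval], min_gap: int = 50, min_length: int = 1
) -> list[TranscriptModel]:
    """Merge stranded reads into single-exon transfrags.

    Per chromosome and strand, maximal runs of reads whose inter-read gap is
    at most ``min_gap`` bp are merged; transfrags shorter than ``min_length``
    are discarded. A desk-scale stand-in for a full spliced assembler.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be non-negative")
    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for r in reads:
        if r.strand not in "+-":
            raise ValueError("reads must be stranded")
        groups.setdefault((r.chrom, r.strand), []).append((r.start, r.end))
    out: list[TranscriptModel] = []
    i = 0
    for chrom, strand in sorted(groups):
        for s, e in merge_pairs(groups[(chrom, strand)], gap=min_gap):
            if e - s >= min_length:
                out.append(TranscriptModel(f"tfrag{i:05d}", chrom, strand, ((s, e),)))
                i += 1
    return out


def tss_supported_transcripts(
    transcripts: Sequence[TranscriptModel],
    peaks: Sequence[PeakRecord],
    min_length: int = 200,
) -> list[TranscriptModel]:
    """Keep transcripts >= ``min_length`` nt whose predicted TSS coordinate
    lies inside a (strandless) peak."""
    index = IntervalIndex([p.interval for p in peaks])
    kept = []
    for t in transcripts:
        if t.length < min_length:
            continue
        probe = GenomicInterval(t.chrom, t.tss, t.tss + 1)
        if index.any_overlap(probe):
            kept.append(t)
    return kept


def classify_genic_context(
    transcripts: Sequence[TranscriptModel],
    pc_genes: Sequence[GenomicInterval],
) -> dict[str, str]:
    """'intragenic' iff the transcript span overlaps any protein-coding gene
    span (TSS to TES, introns included) by >= 1 bp, strand-agnostic; else
    'intergenic'."""
    index = IntervalIndex(list(pc_genes))
    return {
        t.id: "intragenic" if index.any_overlap(t.span) else "intergenic"
        for t in transcripts
    }


def coding_potential_score(
    sequence: str, k: int = 50, seed: int = 0
) -> tuple[float, str]:
    """Shuffle-null coding potential: z-score of the longest forward-strand
    ORF length against ``k`` dinucleotide-preserving shuffles.

    The sign convention matches coding-potential classifiers: negative means
    noncoding. A sequence with no ORF at all is noncoding regardless of the
    (possibly degenerate) null.
    """
    seq = sequence.upper()
    if len(seq) < 200:
        raise ValueError("sequence must be at least 200 nt")
    n_count = seq.count("N")
    if n_count > 0.1 * len(seq):
        raise ValueError("more than 10% N in sequence")
    seq = seq.replace("N", "A")
    rng = np.random.default_rng(seed)
    obs = longest_orf_length(seq)
    null = np.array([longest_orf_length(dinucleotide_shuffle(seq, rng)) for _ in range(k)])
    sd = float(null.std(ddof=0))
    if sd == 0:
        score = 0.0 if obs == null.mean() else float(np.sign(obs - null.mean())) * float("inf")
    else:
        score = (obs - float(null.mean())) / sd
    label = "noncoding" if (score < 0 or obs == 0) else "coding"
    return score, label


def cluster_loci(
    transcripts: Sequence[TranscriptModel],
    context: Mapping[str, str],
    coding_label: Mapping[str, str],
    pc_genes: Sequence[GenomicInterval] = (),
    id_prefix: str = "locus",
) -> list[LocusRecord]:
    """Transitively merge transcripts whose spans (first-exon start to
    last-exon end, so exonic or intronic bases) overlap, strand-agnostic.

    Locus class: ``intergenic_lncRNA`` iff every member is intergenic and
    noncoding; else ``protein_coding`` when a member overlaps an annotated
    gene on the same strand or an intergenic member looks coding; remaining
    loci (opposite-strand overlap only) are ``intragenic_other``.
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    gene_index = IntervalIndex(list(pc_genes))
    loci: list[LocusRecord] = []
    n = 0
    for chrom in sorted(by_chrom):
        ts = sorted(by_chrom[chrom], key=lambda t: (t.start, t.end))
        cluster: list[TranscriptModel] = []
        cluster_end = -1

        def flush() -> None:
            nonlocal n
            if not cluster:
                return
            envelope = GenomicInterval(
                chrom, min(t.start for t in cluster), max(t.end for t in cluster)
            )
            members = sorted(t.id for t in cluster)
            all_lnc = all(
                context[t.id] == "intergenic" and coding_label.get(t.id) == "noncoding"
                for t in cluster
            )
            if all_lnc:
                cls = "intergenic_lncRNA"
            else:
                same_strand_pc = any(
                    gene_index.any_overlap(t.span, strand_aware=True) for t in cluster
                )
                coding_intergenic = any(
                    context[t.id] == "intergenic" and coding_label.get(t.id) == "coding"
                    for t in cluster
                )
                cls = (
                    "protein_coding"
                    if same_strand_pc or coding_intergenic
                    else "intragenic_other"
                )
            loci.append(LocusRecord(f"{id_prefix}{n:05d}", envelope, members, cls))
            n += 1

        for t in ts:
            if cluster and t.start < cluster_end:
                cluster.append(t)
                cluster_end = max(cluster_end, t.end)
            else:
                flush()
                cluster = [t]
                cluster_end = t.end
        flush()
    return loci


def define_promoter(
    transcript: TranscriptModel,
    chrom_length: int | None = None,
    promoter_bp: int = 400,
) -> PromoterRecord:
    """Strand-aware promoter abutting the TSS: ``[tss-400, tss)`` on +,
    ``[tss+1, tss+401)`` on -, truncated at chromosome bounds."""
    tss = transcript.tss
    if transcript.strand == "+":
        start, end = tss - promoter_bp, tss
    else:
        start, end = tss + 1, tss + 1 + promoter_bp
    truncated = False
    if start < 0:
        start, truncated = 0, True
    if chrom_length is not None and end > chrom_length:
        end, truncated = chrom_length, True
    if start >= end:
        return PromoterRecord(transcript.id, None, True)
    return PromoterRecord(
        transcript.id,
        GenomicInterval(transcript.chrom, start, end, transcript.strand),
        truncated,
    )


@dataclass(frozen=True)
class AnnotatedGene:
    """Protein-coding gene annotation entry: gene span plus its annotated
    transcript spans (used for the antisense rule screen)."""

    id: str
    span: GenomicInterval
    tss: int
    transcript_spans: tuple[GenomicInterval, ...] = ()


def identify_antisense(
    transcripts: Sequence[TranscriptModel],
    genes: Sequence[AnnotatedGene],
    peaks: Sequence[PeakRecord],
    artifact_ids: frozenset[str] = frozenset(),
) -> list[AntisenseCall]:
    """Screen transcripts overlapping protein-coding genes on the opposite
    strand.

    Removal rules, applied in order: (i) the transfrag matches an annotated
    coding transcript (same-strand overlap with one); (ii) every peak at its
    own 5' end also contains the host gene's TSS (no independent initiation
    evidence); (iii) no peak at its 5' end at all; (iv) ids on a manual
    artifact exclusion list. Retained calls have reason ``none``.
    """
    gene_index = IntervalIndex([g.span for g in genes])
    span_to_gene = {g.span: g for g in genes}
    annot_tx = IntervalIndex(
        [iv for g in genes for iv in g.transcript_spans]
    )
    peak_index = IntervalIndex([p.interval for p in peaks])
    calls: list[AntisenseCall] = []
    for t in transcripts:
        hosts = [
            span_to_gene[iv]
            for iv in gene_index.overlapping(t.span)
            if iv.strand in "+-" and iv.strand != t.strand
        ]
        if not hosts:
            continue
        host = max(hosts, key=lambda g: t.span.overlap_bp(g.span))
        if t.id in artifact_ids:
            calls.append(AntisenseCall(t.id, host.id, "flagged_artifact"))
            continue
        if annot_tx.any_overlap(t.span, strand_aware=True):
            calls.append(AntisenseCall(t.id, host.id, "annotated_coding"))
            continue
        tss_probe = GenomicInterval(t.chrom, t.tss, t.tss + 1)
        own_peaks = [
            iv for iv in peak_index.overlapping(tss_probe)
        ]
        if not own_peaks:
            calls.append(AntisenseCall(t.id, host.id, "no_5prime_peak"))
            continue
        if all(iv.contains_point(host.tss) for iv in own_peaks):
            calls.append(AntisenseCall(t.id, host.id, "no_independent_peak"))
            continue
        calls.append(AntisenseCall(t.id, host.id, "none"))
    return calls


def detect_bidirectional(
    genes: Sequence[AnnotatedGene],
    reads: Sequence[GenomicInterval],
    window: int = 1000,
) -> list[str]:
    """Gene ids with divergent transcription: at least one read on the
    opposite strand overlapping the +-``window`` bp around the annotated
    TSS (an opposite-strand read near the TSS transcribes away from the
    gene body)."""
    index = IntervalIndex(list(reads))
    hits = []
    for g in genes:
        if g.span.strand not in "+-":
            raise ValueError("genes must be stranded")
        probe = GenomicInterval(
            g.span.chrom, max(0, g.tss - window), g.tss + window + 1
        )
        for r in index.overlapping(probe):
            if r.strand != g.span.strand:
                hits.append(g.id)
                break
    return hits


@dataclass
class AnnotationResult:
    transcripts: list[TranscriptModel]
    context: dict[str, str]
    coding: dict[str, str]
    scores: dict[str, float]
    loci: list[LocusRecord]
    promoters: list[PromoterRecord]


def annotate_pipeline(
    transcripts: Sequence[TranscriptModel],
    peaks: Sequence[PeakRecord],
    pc_genes: Sequence[GenomicInterval],
    genome: Mapping[str, str] | None = None,
    min_length: int = 200,
    cpc_shuffles: int = 50,
    seed: int = 0,
    chrom_lengths: Mapping[str, int] | None = None,
) -> AnnotationResult:
    """Full annotation pass: TSS/length filter, genic context, coding
    potential of intergenic transcripts (when a genome is supplied), locus
    clustering and promoter definition."""
    kept = tss_supported_transcripts(transcripts, peaks, min_length=min_length)
    context = classify_genic_context(kept, pc_genes)
    coding: dict[str, str] = {}
    scores: dict[str, float] = {}
    for t in kept:
        if context[t.id] != "intergenic":
            continue
        if genome is None:
            coding[t.id] = "noncoding"
            continue
        seq = "".join(genome[t.chrom][s:e] for s, e in t.exons)
        if t.strand == "-":
            from .sequences import revcomp

            seq = revcomp(seq)
        score, label = coding_potential_score(seq, k=cpc_shuffles, seed=seed)
        scores[t.id] = score
        coding[t.id] = label
    loci = cluster_loci(kept, context, coding, pc_genes)
    promoters = [
        define_promoter(t, chrom_lengths.get(t.chrom) if chrom_lengths else None)
        for t in kept
    ]
    return AnnotationResult(kept, context, coding, scores, loci, promoters)
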