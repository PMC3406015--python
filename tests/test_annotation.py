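"""Transcript annotation: transfrag assembly, TSS/length filtering, genic
context, coding potential, locus clustering, promoters, antisense rules and
bidirectional-promoter detection."""

import numpy as np
import pytest

from lncturnover.annotate import (
    AnnotatedGene,
    PeakRecord,
    TranscriptModel,
    assemble_transfrags,
    classify_genic_context,
    cluster_loci,
    coding_potential_score,
    define_promoter,
    detect_bidirectional,
    identify_antisense,
    tss_supported_transcripts,
)
from lncturnover.intervals import GenomicInterval
from lncturnover.sequences import dinucleotide_shuffle, longest_orf_length, random_sequence


def iv(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand)


def tx(tid, exons, strand="+", chrom="chr1"):
    return TranscriptModel(tid, chrom, strand, tuple(exons))


def peak(start, end, chrom="chr1"):
    return PeakRecord(GenomicInterval(chrom, start, end), (start + end) // 2)


# ------------------------------------------------------------ transfrags
def test_assemble_merges_overlapping_reads_same_strand():
    reads = [iv("chr1", 100, 200, "+"), iv("chr1", 150, 260, "+")]
    out = assemble_transfrags(reads, min_gap=50)
    assert len(out) == 1
    assert (out[0].start, out[0].end) == (100, 260)


def test_assemble_keeps_strands_separate():
    reads = [iv("chr1", 100, 200, "+"), iv("chr1", 150, 260, "-")]
    out = assemble_transfrags(reads, min_gap=50)
    assert len(out) == 2
    assert {t.strand for t in out} == {"+", "-"}


def test_assemble_rejects_negative_gap():
    with pytest.raises(ValueError):
        assemble_transfrags([iv("chr1", 0, 10, "+")], min_gap=-1)


def test_assemble_matches_interval_union_oracle():
    """1000 random stranded reads: merged transfrags must equal a per-base
    union computed by brute force."""
    rng = np.random.default_rng(42)
    min_gap = 30
    reads = []
    for _ in range(1000):
        s = int(rng.integers(0, 5000))
        reads.append(iv("chr1", s, s + int(rng.integers(20, 80)),
                        "+" if rng.random() < 0.5 else "-"))
    out = assemble_transfrags(reads, min_gap=min_gap)
    for strand in "+-":
        cover = np.zeros(6000, dtype=bool)
        for r in reads:
            if r.strand == strand:
                cover[r.start:r.end] = True
        # brute-force: fuse covered runs separated by <= min_gap
        runs = []
        pos = 0
        while pos < len(cover):
            if cover[pos]:
                start = pos
                while pos < len(cover) and cover[pos]:
                    pos += 1
                runs.append([start, pos])
            else:
                pos += 1
        fused = []
        for s, e in runs:
            if fused and s - fused[-1][1] <= min_gap:
                fused[-1][1] = e
            else:
                fused.append([s, e])
        got = sorted((t.start, t.end) for t in out if t.strand == strand)
        assert got == [tuple(r) for r in fused]


# ------------------------------------------------------------- TSS filter
def test_tss_filter_length_and_peak_rules():
    peaks = [peak(990, 1010)]
    short = tx("short", [(1000, 1150)])           # 150 nt, peak at TSS
    no_peak = tx("nopeak", [(5000, 5500)])        # 500 nt, no peak
    boundary = tx("boundary", [(1000, 1200)])     # exactly 200 nt, peak at TSS
    kept = tss_supported_transcripts([short, no_peak, boundary], peaks)
    assert [t.id for t in kept] == ["boundary"]


def test_tss_filter_uses_tss_coordinate_not_transcript_overlap():
    # peak overlaps the transcript body but not the 5' coordinate
    t = tx("t", [(1000, 1400)], strand="+")
    assert tss_supported_transcripts([t], [peak(1200, 1300)]) == []
    # minus strand: TSS is end-1
    t2 = tx("t2", [(1000, 1400)], strand="-")
    assert [x.id for x in tss_supported_transcripts([t2], [peak(1390, 1410)])] == ["t2"]


def test_adding_peaks_never_removes_transcripts():
    """Filtering is monotone in the peak set."""
    rng = np.random.default_rng(3)
    txs = [tx(f"t{i}", [(int(s), int(s) + 300)]) for i, s in
           enumerate(rng.integers(0, 10_000, 30))]
    peaks1 = [peak(int(p), int(p) + 40) for p in rng.integers(0, 10_000, 10)]
    peaks2 = peaks1 + [peak(int(p), int(p) + 40) for p in rng.integers(0, 10_000, 10)]
    kept1 = {t.id for t in tss_supported_transcripts(txs, peaks1)}
    kept2 = {t.id for t in tss_supported_transcripts(txs, peaks2)}
    assert kept1 <= kept2


# ----------------------------------------------------------- genic context
def test_one_bp_overlap_is_intragenic_and_adjacency_is_not():
    genes = [iv("chr1", 299, 500, "+")]
    t_in = tx("a", [(100, 300)])
    ctx = classify_genic_context([t_in], genes)
    assert ctx["a"] == "intragenic"
    ctx2 = classify_genic_context([tx("b", [(100, 300)])], [iv("chr1", 300, 500, "+")])
    assert ctx2["b"] == "intergenic"


def test_genic_context_matches_brute_force_scan():
    rng = np.random.default_rng(7)
    genes = [iv("chr1", int(s), int(s) + int(rng.integers(100, 800)), "+")
             for s in rng.integers(0, 30_000, 40)]
    txs = [tx(f"t{i}", [(int(s), int(s) + int(rng.integers(100, 600)))])
           for i, s in enumerate(rng.integers(0, 30_000, 500))]
    ctx = classify_genic_context(txs, genes)
    for t in txs:
        brute = any(max(t.start, g.start) < min(t.end, g.end) for g in genes)
        assert (ctx[t.id] == "intragenic") == brute


# --------------------------------------------------------- coding potential
def test_poly_a_has_no_orf_and_is_noncoding():
    score, label = coding_potential_score("A" * 300, k=10, seed=0)
    assert label == "noncoding"


def test_full_length_orf_scores_positive():
    rng = np.random.default_rng(1)
    codons = []
    while len(codons) < 98:
        c = random_sequence(3, 0.5, rng)
        if c not in ("TAA", "TAG", "TGA"):
            codons.append(c)
    seq = "ATG" + "".join(codons) + "TAA"  # single 300-nt ORF
    assert longest_orf_length(seq) == 300
    score, label = coding_potential_score(seq, k=30, seed=4)
    assert score > 0 and label == "coding"


def test_score_matches_manual_shuffle_null():
    """Recompute the z-score with an explicit shuffle loop replaying the
    same seeded stream; the library score must agree exactly."""
    rng = np.random.default_rng(99)
    seq = random_sequence(400, 0.45, rng)
    k, seed = 50, 7
    score, _ = coding_potential_score(seq, k=k, seed=seed)
    rng2 = np.random.default_rng(seed)
    null = np.array([
        longest_orf_length(dinucleotide_shuffle(seq, rng2)) for _ in range(k)
    ])
    expected = (longest_orf_length(seq) - null.mean()) / null.std(ddof=0)
    assert score == pytest.approx(expected, abs=1e-12)


def test_shuffle_preserves_dinucleotide_counts():
    rng = np.random.default_rng(5)
    seq = random_sequence(600, 0.5, rng)
    shuf = dinucleotide_shuffle(seq, rng)

    def dinucs(s):
        from collections import Counter
        return Counter(s[i:i + 2] for i in range(len(s) - 1))

    assert dinucs(seq) == dinucs(shuf)
    assert shuf != seq


def test_coding_potential_rejects_n_rich_input():
    with pytest.raises(ValueError):
        coding_potential_score("N" * 100 + "A" * 200, k=5, seed=0)


# ------------------------------------------------------------ locus clusters
def test_transcripts_sharing_only_intronic_bases_cluster_together():
    # t1 exon [0,100)+[900,1000); t2 sits entirely inside t1's intron
    t1 = tx("t1", [(0, 100), (900, 1000)])
    t2 = tx("t2", [(400, 600)])
    ctx = {"t1": "intergenic", "t2": "intergenic"}
    cod = {"t1": "noncoding", "t2": "noncoding"}
    loci = cluster_loci([t1, t2], ctx, cod)
    assert len(loci) == 1
    assert sorted(loci[0].members) == ["t1", "t2"]
    assert loci[0].locus_class == "intergenic_lncRNA"


def test_disjoint_transcripts_make_distinct_loci():
    t1, t2 = tx("t1", [(0, 100)]), tx("t2", [(500, 700)])
    loci = cluster_loci([t1, t2],
                        {"t1": "intergenic", "t2": "intergenic"},
                        {"t1": "noncoding", "t2": "noncoding"})
    assert len(loci) == 2


def test_mixed_locus_is_not_lncRNA_class():
    t1, t2 = tx("t1", [(0, 400)]), tx("t2", [(200, 600)])
    loci = cluster_loci([t1, t2],
                        {"t1": "intergenic", "t2": "intergenic"},
                        {"t1": "noncoding", "t2": "coding"})
    assert len(loci) == 1
    assert loci[0].locus_class != "intergenic_lncRNA"


def test_clustering_is_a_partition_with_disjoint_envelopes():
    rng = np.random.default_rng(11)
    txs = []
    for i in range(300):
        s = int(rng.integers(0, 50_000))
        txs.append(tx(f"t{i}", [(s, s + int(rng.integers(100, 1500)))],
                      strand="+" if rng.random() < 0.5 else "-"))
    ctx = {t.id: "intergenic" for t in txs}
    cod = {t.id: "noncoding" for t in txs}
    loci = cluster_loci(txs, ctx, cod)
    seen = [m for l in loci for m in l.members]
    assert sorted(seen) == sorted(t.id for t in txs)  # each transcript once
    spans = sorted((l.interval.start, l.interval.end) for l in loci)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2  # envelopes pairwise non-overlapping


# ----------------------------------------------------------------- promoters
@pytest.mark.parametrize(
    "strand,tss_exons,expected",
    [
        ("+", [(1000, 1500)], (600, 1000)),
        ("-", [(600, 1000)], (1000, 1400)),
    ],
)
def test_promoter_geometry(strand, tss_exons, expected):
    rec = define_promoter(tx("t", tss_exons, strand=strand))
    assert (rec.interval.start, rec.interval.end) == expected
    assert not rec.truncated


def test_promoter_truncated_at_chromosome_start():
    rec = define_promoter(tx("t", [(100, 600)], strand="+"))
    assert (rec.interval.start, rec.interval.end) == (0, 100)
    assert rec.truncated


def test_promoter_empty_at_position_zero():
    rec = define_promoter(tx("t", [(0, 500)], strand="+"))
    assert rec.interval is None and rec.truncated


# ----------------------------------------------------------------- antisense
def _host(tss=5000, span=(5000, 9000), strand="+", tx_spans=None):
    spans = tuple(
        GenomicInterval("chr1", s, e, strand) for s, e in (tx_spans or [span])
    )
    return AnnotatedGene("host", GenomicInterval("chr1", *span, strand), tss, spans)


def test_antisense_annotated_coding_removed():
    # antisense transfrag that actually matches an annotated minus-strand transcript
    gene_minus = AnnotatedGene(
        "g2", GenomicInterval("chr1", 5000, 9000, "+"), 5000,
        (GenomicInterval("chr1", 6000, 7000, "-"),),
    )
    t = tx("as1", [(6000, 7000)], strand="-")
    calls = identify_antisense([t], [gene_minus], [])
    assert calls[0].removal_reason == "annotated_coding"


def test_antisense_shared_peak_removed_independent_peak_retained():
    host = _host()
    shared = tx("shared", [(4900, 6000)], strand="-")  # TSS at 5999, peak spans host TSS
    calls = identify_antisense([shared], [host], [peak(4950, 6050)])
    assert calls[0].removal_reason == "no_independent_peak"
    own = tx("own", [(6500, 7500)], strand="-")  # own 5' peak away from host TSS
    calls2 = identify_antisense([own], [host], [peak(7450, 7550)])
    assert calls2[0].removal_reason == "none"


def test_antisense_without_5prime_peak_removed():
    calls = identify_antisense([tx("t", [(6000, 7000)], strand="-")], [_host()], [])
    assert calls[0].removal_reason == "no_5prime_peak"


# --------------------------------------------------------------- bidirectional
def test_bidirectional_window_rule():
    gene = AnnotatedGene("g", GenomicInterval("chr1", 10_000, 15_000, "+"), 10_000)
    near = iv("chr1", 9_500, 9_536, "-")   # 500 bp upstream, opposite strand
    far = iv("chr1", 5_000, 5_036, "-")    # 5 kb upstream
    same = iv("chr1", 9_500, 9_536, "+")   # wrong strand
    assert detect_bidirectional([gene], [near]) == ["g"]
    assert detect_bidirectional([gene], [far]) == []
    assert detect_bidirectional([gene], [same]) == []


def test_bidirectional_matches_window_scan_oracle():
    rng = np.random.default_rng(21)
    genes = []
    for i, s in enumerate(rng.integers(2000, 80_000, 40)):
        strand = "+" if rng.random() < 0.5 else "-"
        span = GenomicInterval("chr1", int(s), int(s) + 2000, strand)
        tss = span.start if strand == "+" else span.end - 1
        genes.append(AnnotatedGene(f"g{i}", span, tss))
    reads = [iv("chr1", int(s), int(s) + 36, "+" if rng.random() < 0.5 else "-")
             for s in rng.integers(0, 85_000, 800)]
    got = set(detect_bidirectional(genes, reads, window=1000))
    for g in genes:
        hit = any(
            r.strand != g.span.strand
            and max(r.start, g.tss - 1000) < min(r.end, g.tss + 1001)
            for r in reads
        )
        assert (g.id in got) == hit
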