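"""Cross-species projection, expression evidence, conservation categories,
exon coverage and turnover contingency statistics."""

import math

import numpy as np
import pytest

from lncturnover.conservation import (
    ConservationCall,
    OrthologyMap,
    SpeciesEvidence,
    SyntenicBlock,
    classify_conservation,
    exon_coverage_fraction,
    expression_evidence_at,
    fisher_two_tailed,
    project_interval,
    turnover_contingency,
)
from lncturnover.intervals import GenomicInterval


def iv(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand)


# ------------------------------------------------------------- projection
def test_projection_shifts_by_block_offset():
    m = OrthologyMap([SyntenicBlock("chr1", 0, 10_000, "rchr1", 1000, "same")])
    out = project_interval(iv("chr1", 200, 500, "+"), m)
    assert out == [iv("rchr1", 1200, 1500, "+")]


def test_projection_outside_blocks_is_none():
    m = OrthologyMap([SyntenicBlock("chr1", 0, 1000, "rchr1", 0, "same")])
    assert project_interval(iv("chr1", 2000, 2500), m) == []


def test_projection_rejects_overlapping_source_blocks():
    with pytest.raises(ValueError):
        OrthologyMap([
            SyntenicBlock("chr1", 0, 1000, "rchr1", 0),
            SyntenicBlock("chr1", 500, 1500, "rchr1", 5000),
        ])


def _per_base_projection(pos, block):
    if block.orientation == "same":
        return block.tgt_start + (pos - block.src_start)
    return block.tgt_start + (block.src_end - 1 - pos)


def test_flipped_straddling_projection_matches_per_base_oracle():
    rng = np.random.default_rng(17)
    blocks = [
        SyntenicBlock("chr1", 0, 4000, "rchr1", 100, "same"),
        SyntenicBlock("chr1", 5000, 9000, "rchr2", 50, "flipped"),
    ]
    m = OrthologyMap(blocks)
    for _ in range(300):
        s = int(rng.integers(0, 9500))
        e = s + int(rng.integers(1, 1200))
        segs = project_interval(iv("chr1", s, e, "+"), m)
        mapped = set()
        for seg in segs:
            mapped |= {(seg.chrom, p) for p in range(seg.start, seg.end)}
        brute = set()
        for p in range(s, e):
            for b in blocks:
                if b.src_start <= p < b.src_end:
                    brute.add((b.tgt_chrom, _per_base_projection(p, b)))
        assert mapped == brute


def test_projection_roundtrips_through_inverted_map():
    blocks = [
        SyntenicBlock("chr1", 100, 3000, "rchr1", 700, "same"),
        SyntenicBlock("chr1", 4000, 6000, "rchr1", 9000, "flipped"),
    ]
    m = OrthologyMap(blocks)
    inv = m.invert()
    rng = np.random.default_rng(2)
    for _ in range(200):
        s = int(rng.integers(100, 5900))
        e = min(s + int(rng.integers(1, 400)), 6000)
        src = iv("chr1", s, e, "+")
        back = []
        for seg in project_interval(src, m):
            back.extend(project_interval(seg, inv))
        cover = sorted((b.start, b.end) for b in back)
        direct = [
            (max(s, b.src_start), min(e, b.src_end))
            for b in blocks
            if max(s, b.src_start) < min(e, b.src_end)
        ]
        merged = []
        for a, c in sorted(cover):
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], c))
            else:
                merged.append((a, c))
        assert merged == sorted(direct)
        assert all(b.strand == "+" for b in back)  # double flip restores strand


# --------------------------------------------------------------- evidence
def test_strict_evidence_requires_peak_and_read():
    region = [iv("chr1", 100, 600, "+")]
    peaks = [iv("chr1", 300, 305)]
    ev = expression_evidence_at(region, peaks, [], mode="strict")
    assert not ev.expressed_strict  # peak but no reads
    reads = [iv("chr1", 200, 236, "+")]
    ev2 = expression_evidence_at(region, [], reads, mode="reads_only")
    assert ev2.expressed_reads_only  # relaxed rule: reads suffice
    ev3 = expression_evidence_at(region, [iv("chr1", 599, 700)], reads, mode="strict")
    assert ev3.expressed_strict  # 1-bp peak overlap + 1 read


def test_read_evidence_is_strand_aware():
    region = [iv("chr1", 100, 600, "+")]
    wrong = [iv("chr1", 200, 236, "-")]
    ev = expression_evidence_at(region, [iv("chr1", 100, 200)], wrong, mode="strict")
    assert ev.peak_overlap and not ev.read_overlap


# ----------------------------------------------------------- classification
def _ev(sp, has=True, peak=True, read=True):
    return SpeciesEvidence(sp, has, peak and has, read and has)


@pytest.mark.parametrize(
    "pattern,expected",
    [
        ((True, True, True), "I"),
        ((True, True, False), "II"),
        ((True, False, False), "III"),
        ((False, True, False), "IV"),
        ((False, False, True), "V"),
    ],
)
def test_category_truth_table(pattern, expected):
    evidence = [
        _ev(sp, has=True, peak=flag, read=flag)
        for sp, flag in zip(("mus", "cas", "rat"), pattern)
    ]
    call = classify_conservation("L", evidence)
    assert call.category == expected


def test_no_outgroup_ortholog_is_excluded():
    evidence = [_ev("mus"), _ev("cas"), SpeciesEvidence("rat", False, False, False)]
    assert classify_conservation("L", evidence).category == "excluded_no_ortholog"


def test_all_false_focal_locus_is_a_contradiction():
    evidence = [
        SpeciesEvidence("mus", True, False, False),
        SpeciesEvidence("cas", True, False, False),
        SpeciesEvidence("rat", True, False, False),
    ]
    with pytest.raises(ValueError, match="annotated as expressed"):
        classify_conservation("L", evidence)


# -------------------------------------------------------------- exon coverage
def test_exon_coverage_extremes():
    m = OrthologyMap([SyntenicBlock("chr1", 0, 10_000, "rchr1", 0, "same")])
    exons = [iv("chr1", 100, 300, "+"), iv("chr1", 500, 700, "+")]
    full = [iv("rchr1", 0, 1000, "+")]
    frac, partial = exon_coverage_fraction(exons, full, m)
    assert frac == 1.0 and not partial
    frac0, _ = exon_coverage_fraction(exons, [], m)
    assert frac0 == 0.0


def test_exon_coverage_matches_per_base_oracle():
    rng = np.random.default_rng(8)
    m = OrthologyMap([SyntenicBlock("chr1", 0, 20_000, "rchr1", 3000, "same")])
    exons = [iv("chr1", int(s), int(s) + 150, "+") for s in (100, 2000, 7000, 12_000)]
    reads = [iv("rchr1", int(s), int(s) + 36, "+") for s in rng.integers(3000, 18_000, 400)]
    frac, _ = exon_coverage_fraction(exons, reads, m)
    covered = 0
    total = 0
    for e in exons:
        for p in range(e.start, e.end):
            total += 1
            tp = 3000 + p
            if any(r.start <= tp < r.end for r in reads):
                covered += 1
    assert frac == pytest.approx(covered / total)


# ----------------------------------------------------------------- contingency
def test_printed_turnover_tables_are_significant():
    assert fisher_two_tailed([[160, 108], [6169, 554]]) < 1e-3
    assert fisher_two_tailed([[30, 238], [75, 6648]]) < 1e-3
    assert fisher_two_tailed([[31, 79], [1326, 1089]]) < 1e-3


def test_identical_proportions_give_p_one():
    assert fisher_two_tailed([[50, 50], [50, 50]]) == pytest.approx(1.0)


def _hypergeom_two_tailed(table):
    """Independent enumeration oracle: sum of hypergeometric probabilities
    of all tables (fixed margins) no more likely than the observed one."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


def test_fisher_matches_enumeration_oracle():
    for table in ([[31, 79], [132, 108]], [[5, 9], [12, 3]], [[2, 8], [7, 4]]):
        assert fisher_two_tailed(table) == pytest.approx(
            _hypergeom_two_tailed(table), rel=1e-9
        )


def test_turnover_contingency_from_calls():
    g1 = [ConservationCall(f"l{i}", "I") for i in range(8)] + [
        ConservationCall(f"l{i+8}", "III") for i in range(2)
    ]
    g2 = [ConservationCall(f"p{i}", "I") for i in range(9)] + [
        ConservationCall("p9", "II")
    ]
    table, p, (prop1, prop2) = turnover_contingency(g1, g2, "I")
    assert table == [[8, 2], [9, 1]]
    assert prop1 == 0.8 and prop2 == 0.9
    assert 0 < p <= 1
    with pytest.raises(ValueError):
        turnover_contingency([], g2, "I")
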