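"""Neighbor pairing, orientation classes, gene territories, permutation
enrichment and expression-shift tests."""

import numpy as np
import pytest
from scipy import stats

from lncturnover.intervals import GenomicInterval
from lncturnover.neighbors import (
    GeneFeature,
    distance_correlation,
    expression_shift_test,
    gene_territories,
    neighbor_pairs,
    orientation_class,
    permutation_enrichment,
)


def feat(fid, start, end, strand="+", chrom="chr1"):
    tss = start if strand == "+" else end - 1
    return GeneFeature(fid, GenomicInterval(chrom, start, end, strand), tss)


# --------------------------------------------------------------- pairing
def test_nearest_gene_becomes_gene_a():
    lnc = feat("lnc", 5000, 6000)
    left = feat("left", 3500, 4500)
    right = feat("right", 8000, 9000)
    pairs = neighbor_pairs([lnc], [left, right])
    assert pairs[0].gene_a == "left" and pairs[0].gene_b == "right"


def test_paralogous_gene_b_is_replaced():
    lnc = feat("lnc", 5000, 6000)
    a = feat("a", 3500, 4500)
    b = feat("b", 8000, 9000)
    c = feat("c", 12_000, 13_000)
    pairs = neighbor_pairs([lnc], [a, b, c], paralogs={frozenset(("a", "b"))})
    assert pairs[0].gene_a == "a" and pairs[0].gene_b == "c"


def test_missing_ortholog_drops_pair_with_reason():
    lnc = feat("lnc", 5000, 6000)
    a, b = feat("a", 3500, 4500), feat("b", 8000, 9000)
    pairs = neighbor_pairs([lnc], [a, b], orthologs={"b"})
    assert pairs[0].drop_reason == "gene_A_no_ortholog"


def test_neighbor_pairs_match_brute_force_scan():
    rng = np.random.default_rng(31)
    for _ in range(40):
        genes = []
        pos = 0
        for i in range(int(rng.integers(3, 12))):
            pos += int(rng.integers(500, 5000))
            end = pos + int(rng.integers(300, 2000))
            genes.append(feat(f"g{i}", pos, end,
                              "+" if rng.random() < 0.5 else "-"))
            pos = end
        s = int(rng.integers(0, pos))
        lnc = feat("lnc", s, s + 400, "+" if rng.random() < 0.5 else "-")
        pairs = neighbor_pairs([lnc], genes)

        def gap(g):
            return max(0, max(lnc.span.start, g.span.start)
                       - min(lnc.span.end, g.span.end))

        ranked = sorted(genes, key=lambda g: (gap(g), g.span.start))
        assert pairs[0].gene_a == ranked[0].id
        assert pairs[0].gene_b == ranked[1].id
        assert pairs[0].tss_distance == abs(lnc.tss - ranked[0].tss)


def test_neighbor_pairs_stable_under_coordinate_shift():
    genes = [feat("a", 1000, 2000, "-"), feat("b", 6000, 7000, "+")]
    lnc = feat("lnc", 3000, 3600, "+")
    base = neighbor_pairs([lnc], genes)[0]
    shift = 12_345
    genes2 = [feat(g.id, g.span.start + shift, g.span.end + shift, g.span.strand)
              for g in genes]
    lnc2 = feat("lnc", 3000 + shift, 3600 + shift, "+")
    moved = neighbor_pairs([lnc2], genes2)[0]
    assert (base.gene_a, base.gene_b, base.orientation, base.tss_distance) == (
        moved.gene_a, moved.gene_b, moved.orientation, moved.tss_distance
    )


# ------------------------------------------------------------- orientation
def test_orientation_geometry():
    # same strand -> tandem
    assert orientation_class(feat("l", 100, 500, "+"), feat("g", 2000, 4000, "+")) == "tandem"
    # lncRNA on the left transcribing leftward, gene rightward -> divergent
    assert orientation_class(feat("l", 100, 500, "-"), feat("g", 2000, 4000, "+")) == "divergent"
    # transcribing toward each other -> convergent
    assert orientation_class(feat("l", 100, 500, "+"), feat("g", 2000, 4000, "-")) == "convergent"
    # mirrored arrangement
    assert orientation_class(feat("l", 5000, 5400, "+"), feat("g", 1000, 2000, "-")) == "divergent"
    with pytest.raises(ValueError):
        orientation_class(feat("l", 0, 10, "+"),
                          GeneFeature("g", GenomicInterval("chr1", 20, 30, "."), 20))


# -------------------------------------------------------------- territories
def test_territory_midpoint_and_single_gene():
    genes = [feat("a", 0, 100), feat("b", 900, 1000)]
    terr = gene_territories(genes, {"chr1": 1000})
    assert terr["a"] == GenomicInterval("chr1", 0, 500)
    assert terr["b"] == GenomicInterval("chr1", 500, 1000)
    solo = gene_territories([feat("x", 400, 600)], {"chr1": 1000})
    assert solo["x"] == GenomicInterval("chr1", 0, 1000)


def test_territories_partition_chromosome_and_assign_nearest_gene():
    rng = np.random.default_rng(41)
    genes = []
    pos = 0
    for i in range(8):
        pos += int(rng.integers(200, 2000))
        end = pos + int(rng.integers(100, 800))
        genes.append(feat(f"g{i}", pos, end))
        pos = end
    clen = pos + 1500
    terr = gene_territories(genes, {"chr1": clen})
    ivs = sorted(terr.values(), key=lambda t: t.start)
    assert ivs[0].start == 0 and ivs[-1].end == clen
    assert sum(t.length for t in ivs) == clen
    for t1, t2 in zip(ivs, ivs[1:]):
        assert t1.end == t2.start
    # per-base check: each base belongs to the gene with the nearest envelope
    probes = rng.integers(0, clen, 400)
    for p in probes:
        p = int(p)
        owner = next(g.id for g in genes
                     if terr[g.id].start <= p < terr[g.id].end)
        def env_dist(g):
            return max(0, max(p + 1, g.span.start) - min(p, g.span.end),
                       g.span.start - p if p < g.span.start else 0)
        dists = {g.id: (max(g.span.start - p, 0, p + 1 - g.span.end)) for g in genes}
        assert dists[owner] == min(dists.values())


# ------------------------------------------------------------- permutation
def test_annotation_covering_workspace_gives_fold_one():
    ws = [GenomicInterval("chr1", 0, 10_000)]
    segs = [GenomicInterval("chr1", 100, 400), GenomicInterval("chr1", 5000, 5600)]
    res = permutation_enrichment(segs, ws, ws, n_perms=99, seed=0)
    assert res.fold == pytest.approx(1.0)
    assert res.p == pytest.approx(1.0)


def test_tiny_instance_matches_exhaustive_enumeration():
    """Workspace 100 bp, one 10-bp segment: the empirical p must approach
    the exhaustive placement enumeration."""
    ws = [GenomicInterval("chr1", 0, 100)]
    ann = [GenomicInterval("chr1", 80, 100)]
    seg = [GenomicInterval("chr1", 85, 95)]  # observed overlap 10
    res = permutation_enrichment(seg, ann, ws, n_perms=20_000, seed=3)
    # enumerate all 91 placements of a 10-bp segment
    overlaps = [max(0, min(s + 10, 100) - max(s, 80)) for s in range(91)]
    exact_p = sum(o >= 10 for o in overlaps) / len(overlaps)
    assert res.direction == "enrichment"
    assert res.p == pytest.approx(exact_p, abs=0.01)
    assert res.expected_mean == pytest.approx(np.mean(overlaps), rel=0.05)


def test_oversized_segment_raises():
    ws = [GenomicInterval("chr1", 0, 50)]
    with pytest.raises(ValueError, match="fits in no workspace"):
        permutation_enrichment(
            [GenomicInterval("chr1", 0, 60)], ws, ws, n_perms=99
        )


def test_null_permutation_p_values_are_superuniform():
    """200 null scenarios (segments placed by the same law as the
    randomization): the p-value distribution must not be anti-conservative."""
    rng = np.random.default_rng(51)
    ws = [GenomicInterval("chr1", 0, 20_000)]
    ann = [GenomicInterval("chr1", 4000, 8000)]
    ps = []
    for _ in range(200):
        segs = []
        for _ in range(3):
            s = int(rng.integers(0, 20_000 - 300))
            segs.append(GenomicInterval("chr1", s, s + 300))
        res = permutation_enrichment(segs, ann, ws, n_perms=99,
                                     seed=int(rng.integers(2**31)))
        ps.append(res.p_enrichment)
    # one-sided KS: empirical CDF should not exceed the uniform CDF
    ks = stats.kstest(ps, "uniform", alternative="greater")
    assert ks.pvalue > 0.01
    # the reported directional p must also be valid at conventional levels
    assert np.mean(np.array([p for p in ps]) <= 0.05) <= 0.10


# ------------------------------------------------------------ shift tests
def test_all_zero_folds_show_no_shift():
    groups = {"gene_A": [0.0] * 30, "gene_B": [0.0] * 30}
    res = expression_shift_test(groups, [0.0] * 50)
    assert res["gene_A"].median == 0.0
    assert res["gene_A"].p is None or res["gene_A"].p >= 0.05


def test_small_groups_reported_underpowered():
    res = expression_shift_test({"tiny": [0.5, 0.4]}, [0.0] * 50)
    assert res["tiny"].p is None and res["tiny"].note == "underpowered"


def test_planted_shift_detected_only_in_target_group():
    rng = np.random.default_rng(61)
    baseline = rng.normal(0, 0.5, 230)
    shifted = rng.normal(np.log(1.25), 0.5, 150)
    untouched = rng.normal(0, 0.5, 120)
    res = expression_shift_test(
        {"gene_A": shifted, "gene_B": untouched}, baseline
    )
    assert res["gene_A"].p < 0.05
    assert res["gene_B"].p > 0.05


# ------------------------------------------------------ distance correlation
def test_distance_correlation_cases():
    rng = np.random.default_rng(71)
    d = rng.uniform(1e3, 1e6, 137)
    # constant folds -> undefined
    r, p, ok = distance_correlation(d, np.zeros(137))
    assert not ok
    # perfectly linear in log10 distance -> r = 1
    r, p, ok = distance_correlation(d, np.log10(d) * 2.0 + 1.0)
    assert ok and r == pytest.approx(1.0)
    # distance-independent elevation -> weak correlation
    r, p, ok = distance_correlation(d, rng.normal(0.2, 0.5, 137))
    assert ok and abs(r) < 0.2
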