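"""Synthetic multi-species scenario generator with planted truth.

Emulates a three-rodent liver transcriptome study: a focal mouse taxon and
a sister taxon annotated on the same assembly, plus an outgroup genome
related through co-linear syntenic blocks. The generator lays out
protein-coding genes, intergenic lncRNA loci in the five transcriptional
conservation categories (I all three species ... V outgroup only),
ancestral repeats and indel-purified segments; emits per-species promoter
peaks, stranded read libraries, gene count tables and pairwise alignments
evolved at feature-class-specific substitution rates; and writes a
planted-truth sidecar so every downstream stage can be scored against what
was planted.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import PeakRecord, TranscriptModel
from .conservation import OrthologyMap, SyntenicBlock, project_interval
from .constraint import PairwiseAlignment
from .intervals import GenomicInterval, merge_pairs, subtract_pairs, intersect_pairs, total_length
from .neighbors import GeneFeature, gene_territories
from .revmodel import RevParams, encode, decode, transition_probabilities
from .sequences import random_sequence, remove_start_codons, revcomp

CATEGORY_SPECIES = {
    # which of (focal, sister, outgroup) transcribe a lncRNA of each category
    "I": (True, True, True),
    "II": (True, True, False),
    "III": (True, False, False),
    "IV": (False, True, False),
    "V": (False, False, True),
}

DEFAULT_BRANCH_RATES = {
    "conserved_lncRNA": 0.148,
    "lineage_lncRNA": 0.164,
    "pc_exon": 0.079,
    "pc_intron": 0.162,
    "promoter_conserved": 0.128,
    "promoter_lineage": 0.148,
    "AR": 0.164,
}


@dataclass
class ExpressionConfig:
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    # per-species lognormal noise; a between-species fold combines two draws
    # (0.30/species reproduces the study's housekeeping-baseline dispersion)
    between_species_sd: float = 0.30
    neighbor_elevation_fraction: float = 0.25
    library_scale_per_species: dict = field(
        default_factory=lambda: {"mus": 1.0, "cas": 1.0, "rat": 1.0}
    )


@dataclass
class ScenarioConfig:
    seed: int = 0
    species: tuple[str, str, str] = ("mus", "cas", "rat")  # focal, sister, outgroup
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_200_000}
    )
    n_protein_coding: int = 300
    n_lncRNA_per_category: dict = field(
        default_factory=lambda: {"I": 10, "II": 10, "III": 10, "IV": 10, "V": 10}
    )
    read_depth_per_species: dict = field(
        default_factory=lambda: {"mus": 60_000, "cas": 30_000, "rat": 50_000}
    )
    mean_transcript_length: int = 1500
    branch_rates: dict = field(default_factory=lambda: dict(DEFAULT_BRANCH_RATES))
    gc_range: tuple[float, float] = (0.40, 0.48)
    n_ARs: int = 150
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    n_housekeeping: int = 60
    n_paralog_pairs: int = 10
    n_lineage_pc: int = 15
    liver_gene_fraction: float = 0.35
    territory_enrichment_fold: float = 1.6
    n_indel_purified: int = 60
    indel_purified_length: int = 500
    indel_purified_fold: float = 1.6
    read_length: int = 36

    def __post_init__(self) -> None:
        counts = [
            self.n_protein_coding,
            self.n_ARs,
            self.n_housekeeping,
            self.n_paralog_pairs,
            self.n_lineage_pc,
            *self.n_lncRNA_per_category.values(),
            *self.read_depth_per_species.values(),
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if not set(self.n_lncRNA_per_category) <= set(CATEGORY_SPECIES):
            raise ValueError("lncRNA categories must be within I..V")
        if self.branch_rates["conserved_lncRNA"] > self.branch_rates["AR"]:
            raise ValueError(
                "conserved lncRNA rate must not exceed the neutral AR rate "
                "(the planted constraint signal)"
            )
        if self.expression.neighbor_elevation_fraction < 0:
            raise ValueError("elevation fraction must be non-negative")


@dataclass
class PCGene:
    id: str
    chrom: str
    strand: str
    isoforms: list[tuple[tuple[int, int], ...]]  # each a sorted exon chain

    @property
    def start(self) -> int:
        return min(e[0][0] for e in self.isoforms)

    @property
    def end(self) -> int:
        return max(e[-1][1] for e in self.isoforms)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def feature(self) -> GeneFeature:
        return GeneFeature(self.id, self.span, self.tss)


@dataclass
class LncLocus:
    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    category: str

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0][0], self.exons[-1][1], self.strand)

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    def transcript(self) -> TranscriptModel:
        return TranscriptModel(self.id, self.chrom, self.strand, self.exons)


@dataclass
class PlantedTruth:
    """Sidecar with everything the generator decided, for scoring."""

    lnc_categories: dict  # lnc id -> category
    lnc_loci: dict  # lnc id -> dict(chrom, start, end, strand, tss)
    region_rates: dict  # region id -> true substitutions/site
    gene_expression: dict  # gene id -> dict(lambda per species, elevated_in, housekeeping, liver, lineage_pc)
    library_scales: dict
    territory_fold: float
    indel_purified_fold: float

    def to_dict(self) -> dict:
        return {
            "lnc_categories": self.lnc_categories,
            "lnc_loci": self.lnc_loci,
            "region_rates": self.region_rates,
            "gene_expression": self.gene_expression,
            "library_scales": self.library_scales,
            "territory_fold": self.territory_fold,
            "indel_purified_fold": self.indel_purified_fold,
        }


@dataclass
class ScenarioBundle:
    config: ScenarioConfig
    chrom_lengths: dict  # focal/sister assembly
    outgroup_chrom_lengths: dict
    genomes: dict  # species -> chrom -> str
    genes: list  # list[PCGene] (focal coordinates; outgroup via projection)
    lnc_loci: list  # list[LncLocus]
    peaks: dict  # species -> list[PeakRecord]
    reads: dict  # species -> list[GenomicInterval]
    ars: list  # list[(ar_id, GenomicInterval, gc)]
    indel_purified: list  # list[GenomicInterval]
    maps: dict  # species -> OrthologyMap from focal coordinates
    counts: pd.DataFrame  # index gene id, one column per species
    orthologs: pd.DataFrame  # columns focal_gene, outgroup_gene
    paralogs: list  # list[tuple[str, str]]
    housekeeping: list  # gene ids
    liver_genes: list  # gene ids
    alignments: dict  # feature class -> list[PairwiseAlignment]
    truth: PlantedTruth

    # -- convenience views ------------------------------------------------
    @property
    def focal(self) -> str:
        return self.config.species[0]

    def gene_features(self) -> list[GeneFeature]:
        return [g.feature() for g in self.genes]

    def lnc_features(self) -> list[GeneFeature]:
        return [GeneFeature(l.id, l.span, l.tss) for l in self.lnc_loci]


class PlacementError(ValueError):
    """Raised when the requested feature load does not fit in the genome."""


def _mutate_sequence(seq: str, d: float, params: RevParams, rng: np.random.Generator) -> str:
    """Evolve a sequence for distance d under the REV model (per-site
    independent transition sampling)."""
    if d == 0:
        return seq
    P = transition_probabilities(params, d)
    codes = encode(seq)
    if np.any(codes < 0):
        raise ValueError("sequence must be ACGT")
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(codes))
    out = (u[:, None] < cum[codes]).argmax(axis=1)
    return decode(out)


def evolve_pair(
    length: int,
    d: float,
    rev_params: RevParams = RevParams(),
    seed: int = 0,
    region_id: str = "pair",
    feature_class: str = "locus",
) -> PairwiseAlignment:
    """Gap-free aligned sequence pair at REV distance ``d``.

    The first sequence is drawn from the stationary composition and the
    second is its descendant after distance ``d``; by time-reversibility the
    pair has the correct joint distribution for a two-taxon alignment.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    rng = np.random.default_rng(seed)
    pi = rev_params.pi
    anc_codes = rng.choice(4, size=length, p=pi)
    seq1 = decode(anc_codes)
    seq2 = _mutate_sequence(seq1, d, rev_params, rng)
    return PairwiseAlignment(region_id, seq1, seq2, feature_class)


def simulate_read_library(
    transcripts: Sequence[TranscriptModel],
    depth: int,
    seed: int = 0,
    weights: Sequence[float] | None = None,
    read_length: int = 36,
    ensure_each: bool = False,
) -> list[GenomicInterval]:
    """Stranded single-end reads drawn from transcript exons.

    Reads fall entirely within one exon on the transcript's strand; the
    total equals ``depth`` exactly. ``weights`` are relative expression
    levels (uniform when omitted); with ``ensure_each`` every transcript
    receives at least one read (requires ``depth >= len(transcripts)``).
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if depth == 0:
        return []
    if not transcripts:
        raise ValueError("cannot draw reads from an empty transcript set")
    rng = np.random.default_rng(seed)
    w = np.ones(len(transcripts)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    if ensure_each:
        if depth < len(transcripts):
            raise ValueError("depth too small to guarantee a read per transcript")
        counts = np.ones(len(transcripts), dtype=int)
        counts += rng.multinomial(depth - len(transcripts), w)
    else:
        counts = rng.multinomial(depth, w)
    reads: list[GenomicInterval] = []
    for t, n in zip(transcripts, counts):
        if n == 0:
            continue
        ex_lens = np.array([e - s for s, e in t.exons], dtype=float)
        exon_idx = rng.choice(len(t.exons), size=n, p=ex_lens / ex_lens.sum())
        for i in exon_idx:
            s, e = t.exons[int(i)]
            if e - s <= read_length:
                reads.append(GenomicInterval(t.chrom, s, e, t.strand))
            else:
                start = int(rng.integers(s, e - read_length + 1))
                reads.append(GenomicInterval(t.chrom, start, start + read_length, t.strand))
    return reads


# ---------------------------------------------------------------------------
# scenario assembly


def _largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * total
    out = np.floor(raw).astype(int)
    rem = total - out.sum()
    order = np.argsort(-(raw - out))
    for k in range(rem):
        out[order[k]] += 1
    return out.tolist()


def _gene_structure(rng: np.random.Generator, mean_len: int) -> tuple[list[int], list[int]]:
    """Exon and intron lengths for one protein-coding gene."""
    n_exons = int(rng.integers(2, 6))
    per = max(150, mean_len // n_exons)
    exon_lens = [int(rng.integers(per // 2, per + per // 2)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(200, 800)) for _ in range(n_exons - 1)]
    return exon_lens, intron_lens


def _sample_position(
    rng: np.random.Generator, free: Mapping[str, list[tuple[int, int]]], length: int
) -> tuple[str, int] | None:
    """Uniform start position over all free intervals where ``length`` fits."""
    chroms, starts, rooms = [], [], []
    for chrom in sorted(free):
        for s, e in free[chrom]:
            room = e - s - length + 1
            if room > 0:
                chroms.append(chrom)
                starts.append(s)
                rooms.append(room)
    if not rooms:
        return None
    cum = np.cumsum(rooms)
    r = int(rng.integers(cum[-1]))
    j = int(np.searchsorted(cum, r, side="right"))
    offset = int(r - (cum[j - 1] if j > 0 else 0))
    return chroms[j], int(starts[j]) + offset


def _remove_from_free(
    free: dict[str, list[tuple[int, int]]], chrom: str, start: int, end: int
) -> None:
    if chrom in free:
        free[chrom] = subtract_pairs(free[chrom], [(start, end)])


def _orf_sequence(length: int, rng: np.random.Generator) -> str:
    """mRNA-like sequence: one ORF spanning (almost) the whole length."""
    n_codons = max(2, length // 3)
    body = []
    while len(body) < n_codons - 2:
        codon = random_sequence(3, 0.5, rng)
        if codon not in ("TAA", "TAG", "TGA"):
            body.append(codon)
    seq = "ATG" + "".join(body) + "TAA"
    tail = length - len(seq)
    if tail > 0:
        seq += random_sequence(tail, 0.5, rng)
    return seq[:length]


def _noncoding_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence with every start codon removed: its longest ORF (and
    that of any substring an assembler might recover) is exactly zero, so
    the coding-potential screen labels it noncoding unambiguously."""
    from .sequences import longest_orf_length

    seq = remove_start_codons(random_sequence(length, gc, rng))
    assert longest_orf_length(seq) == 0
    return seq


def generate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Build a complete multi-species scenario with planted truth.

    Deterministic for a given config and seed. Raises
    :class:`PlacementError` when the requested features cannot be placed
    without overlap in the configured genome.
    """
    rng = np.random.default_rng(config.seed)
    focal, sister, outgroup = config.species
    gc = float(np.mean(config.gc_range))
    chroms = sorted(config.chrom_lengths)
    lengths = [config.chrom_lengths[c] for c in chroms]

    # ---- protein-coding gene layout (focal coordinates) -----------------
    per_chrom = _largest_remainder(config.n_protein_coding, lengths)
    genes: list[PCGene] = []
    gid = 0
    min_gap = 6000  # leaves room for lncRNAs / ARs between genes
    for chrom, clen, n in zip(chroms, lengths, per_chrom):
        structures = [_gene_structure(rng, config.mean_transcript_length) for _ in range(n)]
        spans = [sum(e) + sum(i) for e, i in structures]
        free = clen - sum(spans) - (n + 1) * min_gap
        if free < 0:
            raise PlacementError(
                f"{n} genes need {sum(spans) + (n + 1) * min_gap} bp on {chrom} "
                f"but it is only {clen} bp long"
            )
        extra = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
        pos = min_gap + int(extra[0])
        for k, (exon_lens, intron_lens) in enumerate(structures):
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            cur = pos
            for i, el in enumerate(exon_lens):
                exons.append((cur, cur + el))
                cur += el
                if i < len(intron_lens):
                    cur += intron_lens[i]
            isoforms = [tuple(exons)]
            if len(exons) >= 3 and rng.random() < 0.35:
                skip = int(rng.integers(1, len(exons) - 1))
                isoforms.append(tuple(e for i, e in enumerate(exons) if i != skip))
            genes.append(PCGene(f"gene{gid:04d}", chrom, strand, isoforms))
            gid += 1
            pos = cur + min_gap + int(extra[k + 1])

    gene_feats = [g.feature() for g in genes]
    # fixed liver-gene count per chromosome (balanced shares keep the
    # planted territory enrichment calibrated against the per-chromosome
    # randomization null)
    liver_flags = np.zeros(len(genes), dtype=bool)
    for chrom in chroms:
        idx = [i for i, g in enumerate(genes) if g.chrom == chrom]
        take = int(round(config.liver_gene_fraction * len(idx)))
        chosen = rng.permutation(len(idx))[:take]
        for k in chosen:
            liver_flags[idx[int(k)]] = True
    liver_genes = [g.id for g, f in zip(genes, liver_flags) if f]
    territories = gene_territories(gene_feats, config.chrom_lengths)

    # intergenic workspace: everything at least 500 bp away from a gene
    workspace: dict[str, list[tuple[int, int]]] = {}
    for chrom, clen in zip(chroms, lengths):
        spans = [
            (max(0, g.start - 500), min(clen, g.end + 500)) for g in genes if g.chrom == chrom
        ]
        workspace[chrom] = subtract_pairs([(0, clen)], spans)
    liver_ws: dict[str, list[tuple[int, int]]] = {}
    nonliver_ws: dict[str, list[tuple[int, int]]] = {}
    for chrom in chroms:
        liver_terr = [
            (territories[g.id].start, territories[g.id].end)
            for g, f in zip(genes, liver_flags)
            if f and g.chrom == chrom
        ]
        liver_ws[chrom] = intersect_pairs(workspace[chrom], liver_terr)
        nonliver_ws[chrom] = subtract_pairs(workspace[chrom], liver_terr)
    ws_total = sum(total_length(p) for p in workspace.values())

    # ---- lncRNA loci -----------------------------------------------------
    categories = [
        cat
        for cat in ("I", "II", "III", "IV", "V")
        for _ in range(config.n_lncRNA_per_category.get(cat, 0))
    ]
    categories = [categories[i] for i in rng.permutation(len(categories))]
    n_lnc = len(categories)
    geoms: list[tuple[list[int], list[int]]] = []
    for _ in range(n_lnc):
        n_exons = 1 if rng.random() < 0.6 else 2
        tx_len = int(np.clip(rng.normal(0.6 * config.mean_transcript_length, 200), 600, 1400))
        if n_exons == 1:
            geoms.append(([tx_len], []))
        else:
            # short introns: lncRNAs here are compact two-exon genes
            first = tx_len // 2
            geoms.append(([first, tx_len - first], [int(rng.integers(100, 250))]))
    span_lens = [sum(e) + sum(i) for e, i in geoms]

    # the enrichment in liver-expressed territories is planted relative to
    # the randomization null: compute the placement-weighted liver share of
    # the workspace exactly (placements taper near gap edges, so it differs
    # from the raw base-pair share) and put fold x that fraction of lncRNA
    # nucleotides into liver territories, stratified per category
    liver_S: dict[str, np.ndarray] = {}
    for chrom, clen in zip(chroms, lengths):
        ind = np.zeros(clen, dtype=np.int64)
        for s, e in liver_ws.get(chrom, []):
            ind[s:e] = 1
        cum = np.concatenate([[0], np.cumsum(ind)])  # cum[i] = liver bp in [0, i)
        liver_S[chrom] = np.concatenate([[0], np.cumsum(cum)])  # S[k] = sum_{i<k} cum[i]

    def _null_liver_share(span_len: int) -> float:
        """Exact E[liver overlap]/span_len over uniform placements that fit
        inside a single workspace interval, pooled over chromosomes."""
        num = 0.0
        n_tot = 0
        for chrom in chroms:
            S = liver_S[chrom]
            for s, e in workspace[chrom]:
                n = e - s - span_len + 1
                if n <= 0:
                    continue
                # sum over starts x in [s, e-L] of cum[x+L] - cum[x]
                num += (S[e + 1] - S[s + span_len]) - (S[s + n] - S[s])
                n_tot += n
        return num / (n_tot * span_len) if n_tot else 0.0

    shares = np.array([_null_liver_share(L) for L in span_lens]) if n_lnc else np.array([])
    w_liver = float(np.average(shares, weights=span_lens)) if n_lnc else 0.0
    p_liver = min(1.0, config.territory_enrichment_fold * w_liver)
    # length-aware greedy allocation keeps the planted liver share of lncRNA
    # nucleotides close to p_liver within every category
    in_liver_flags = np.zeros(n_lnc, dtype=bool)
    for cat in CATEGORY_SPECIES:
        idx = [i for i, c in enumerate(categories) if c == cat]
        if not idx:
            continue
        order = [idx[int(k)] for k in rng.permutation(len(idx))]
        target = p_liver * sum(span_lens[i] for i in idx)
        acc = 0.0
        for i in order:
            if abs(acc + span_lens[i] - target) < abs(acc - target):
                in_liver_flags[i] = True
                acc += span_lens[i]

    lnc_loci: list[LncLocus] = []
    liver_free = copy.deepcopy(liver_ws)
    nonliver_free = copy.deepcopy(nonliver_ws)
    for i, cat in enumerate(categories):
        exon_lens, intron = geoms[i]
        span_len = span_lens[i]
        in_liver = bool(in_liver_flags[i])
        pool = liver_free if in_liver else nonliver_free
        alt = nonliver_free if in_liver else liver_free
        placed = _sample_position(rng, pool, span_len + 600)
        if placed is None:
            placed = _sample_position(rng, alt, span_len + 600)
        if placed is None:
            raise PlacementError(
                f"no intergenic room left for lncRNA locus {i} of span {span_len} bp"
            )
        chrom, start = placed
        start += 300  # clearance inside the sampled slot
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        cur = start
        for k, el in enumerate(exon_lens):
            exons.append((cur, cur + el))
            cur += el
            if k < len(intron):
                cur += intron[k]
        lnc_loci.append(LncLocus(f"lnc{i:04d}", chrom, strand, tuple(exons), cat))
        for free in (liver_free, nonliver_free):
            _remove_from_free(free, chrom, start - 300, cur + 300)

    # ---- ancestral repeats and indel-purified segments -------------------
    remaining = {
        c: merge_pairs(liver_free.get(c, []) + nonliver_free.get(c, [])) for c in chroms
    }
    ars_iv: list[GenomicInterval] = []
    for i in range(config.n_ARs):
        ar_len = int(rng.integers(300, 601))
        placed = _sample_position(rng, remaining, ar_len + 200)
        if placed is None:
            raise PlacementError(f"no room left for ancestral repeat {i}")
        chrom, start = placed
        start += 100
        ars_iv.append(GenomicInterval(chrom, start, start + ar_len))
        _remove_from_free(remaining, chrom, start - 100, start + ar_len + 100)

    lnc_total = sum(l.span.length for l in lnc_loci)
    w_lnc = lnc_total / ws_total if ws_total else 0.0
    p_ips = min(1.0, config.indel_purified_fold * w_lnc)
    ips: list[GenomicInterval] = []
    for i in range(config.n_indel_purified):
        L = config.indel_purified_length
        if lnc_loci and rng.random() < p_ips:
            host = lnc_loci[int(rng.integers(len(lnc_loci)))]
            span = host.span
            if span.length > L:
                s = span.start + int(rng.integers(span.length - L + 1))
            else:
                s = span.start
            ips.append(GenomicInterval(span.chrom, s, s + L))
        else:
            placed = _sample_position(rng, workspace, L)
            if placed is None:
                raise PlacementError("no workspace room for indel-purified segment")
            chrom, s = placed
            ips.append(GenomicInterval(chrom, s, s + L))
    ips.sort()

    # ---- orthology maps --------------------------------------------------
    blocks: list[SyntenicBlock] = []
    outgroup_chrom_lengths: dict[str, int] = {}
    for ci, (chrom, clen) in enumerate(zip(chroms, lengths)):
        tgt = f"rchr{ci + 1}"
        if ci % 2 == 0:
            split = clen // 2 + int(rng.integers(-20_000, 20_000))
            pad1, pad2 = 15_000, 25_000
            blocks.append(SyntenicBlock(chrom, 0, split, tgt, pad1, "same"))
            blocks.append(SyntenicBlock(chrom, split, clen, tgt, pad1 + split + pad2, "same"))
            outgroup_chrom_lengths[tgt] = pad1 + clen + pad2 + 10_000
        else:
            pad = 10_000
            blocks.append(SyntenicBlock(chrom, 0, clen, tgt, pad, "flipped"))
            outgroup_chrom_lengths[tgt] = clen + 2 * pad
    out_map = OrthologyMap(blocks)
    maps = {sister: OrthologyMap.identity(), outgroup: out_map}

    # ---- genome sequences ------------------------------------------------
    focal_genome = {c: bytearray(random_sequence(l, gc, rng), "ascii") for c, l in zip(chroms, lengths)}

    def write_seq(chrom: str, start: int, seq: str) -> None:
        focal_genome[chrom][start : start + len(seq)] = seq.encode()

    for g in genes:
        exons = g.isoforms[0]
        mrna_len = sum(e - s for s, e in exons)
        mrna = _orf_sequence(mrna_len, rng)
        ordered = exons if g.strand == "+" else tuple(reversed(exons))
        off = 0
        for s, e in ordered:
            part = mrna[off : off + (e - s)]
            write_seq(g.chrom, s, part if g.strand == "+" else revcomp(part))
            off += e - s
    for l in lnc_loci:
        # sculpt the whole span (introns included): assembled transfrags are
        # genomic substrings and must also score noncoding
        span = l.span
        seq = _noncoding_sequence(span.length, gc, rng)
        write_seq(span.chrom, span.start, seq if l.strand == "+" else revcomp(seq))
    focal_seqs = {c: bytes(b).decode() for c, b in focal_genome.items()}

    jc = RevParams()
    sister_seqs = {
        c: _mutate_sequence(s, 0.01, jc, rng) for c, s in sorted(focal_seqs.items())
    }
    out_seqs: dict[str, str] = {}
    for tgt, tlen in sorted(outgroup_chrom_lengths.items()):
        out_seqs[tgt] = random_sequence(tlen, gc, rng)
    ar_rate = config.branch_rates["AR"]
    for b in blocks:
        seg = _mutate_sequence(focal_seqs[b.src_chrom][b.src_start : b.src_end], ar_rate, jc, rng)
        if b.orientation == "flipped":
            seg = revcomp(seg)
        s = out_seqs[b.tgt_chrom]
        out_seqs[b.tgt_chrom] = s[: b.tgt_start] + seg + s[b.tgt_start + len(seg) :]
    genomes = {focal: focal_seqs, sister: sister_seqs, outgroup: out_seqs}

    ars = []
    for i, iv in enumerate(sorted(ars_iv)):
        seq = focal_seqs[iv.chrom][iv.start : iv.end]
        gc_frac = (seq.count("G") + seq.count("C")) / len(seq)
        ars.append((f"AR{i:04d}", iv, round(gc_frac, 4)))

    # ---- peaks and reads per species ------------------------------------
    lineage_pc_ids = set(
        g.id for g in [genes[int(i)] for i in rng.choice(len(genes), size=config.n_lineage_pc, replace=False)]
    )

    def active_in(species_idx: int, lnc: LncLocus) -> bool:
        return CATEGORY_SPECIES[lnc.category][species_idx]

    def pc_active(species_idx: int, gene: PCGene) -> bool:
        return not (species_idx == 2 and gene.id in lineage_pc_ids)

    def project_or_none(iv: GenomicInterval, sp: str) -> GenomicInterval | None:
        if sp == focal:
            return iv
        segs = project_interval(iv, maps[sp])
        if not segs:
            return None
        return max(segs, key=lambda s: s.length)

    # H3K4me3 enrichment forms ~1-kb domains around active TSSs
    peaks: dict[str, list[PeakRecord]] = {sp: [] for sp in config.species}
    half_peak = 500
    for si, sp in enumerate(config.species):
        feats: list[tuple[str, GenomicInterval, int]] = []
        for g in genes:
            if pc_active(si, g):
                feats.append((g.id, g.span, g.tss))
        for l in lnc_loci:
            if active_in(si, l):
                feats.append((l.id, l.span, l.tss))
        for _, span, tss in feats:
            probe = GenomicInterval(span.chrom, max(0, tss - half_peak), tss + half_peak)
            proj = project_or_none(probe, sp)
            if proj is None:
                continue
            summit = proj.start + proj.length // 2
            peaks[sp].append(PeakRecord(GenomicInterval(proj.chrom, proj.start, proj.end), summit))
        peaks[sp].sort(key=lambda p: (p.interval.chrom, p.interval.start))

    # planted per-gene expression
    exp_cfg = config.expression
    lam_base = np.exp(rng.normal(exp_cfg.baseline_log_mean, exp_cfg.baseline_log_sd, len(genes)))
    species_noise = {
        sp: np.exp(rng.normal(0.0, exp_cfg.between_species_sd, len(genes)))
        for sp in config.species
    }
    # nearest gene (envelope distance) per lncRNA determines elevation targets
    elevated_in: dict[str, str] = {}
    for l in lnc_loci:
        cands = [g for g in gene_feats if g.span.chrom == l.span.chrom]
        if not cands:
            continue
        nearest = min(cands, key=lambda g: (l.span.distance_to(g.span), g.span.start))
        if l.category in ("II", "III"):
            elevated_in[nearest.id] = focal
        elif l.category == "IV":
            elevated_in[nearest.id] = sister
        elif l.category == "V":
            elevated_in[nearest.id] = outgroup
    lam: dict[str, np.ndarray] = {}
    for sp in config.species:
        scale = exp_cfg.library_scale_per_species.get(sp, 1.0)
        arr = lam_base * species_noise[sp] * scale
        for gi, g in enumerate(genes):
            if elevated_in.get(g.id) == sp:
                arr[gi] *= 1.0 + exp_cfg.neighbor_elevation_fraction
        lam[sp] = arr
    counts = pd.DataFrame(
        {sp: rng.poisson(lam[sp]) for sp in config.species},
        index=[g.id for g in genes],
    )
    counts.index.name = "gene"

    # reads: weights follow the planted expression; lncRNAs get their own draw
    # lncRNAs are lowly expressed relative to genes, but planted loci model
    # the *detected* catalogue, so their coverage floor keeps them assemblable
    lnc_weight = np.exp(rng.normal(exp_cfg.baseline_log_mean - 0.4, 0.4, len(lnc_loci)))
    reads: dict[str, list[GenomicInterval]] = {}
    for si, sp in enumerate(config.species):
        tx: list[TranscriptModel] = []
        wts: list[float] = []
        for gi, g in enumerate(genes):
            if not pc_active(si, g):
                continue
            tx.append(TranscriptModel(g.id, g.chrom, g.strand, g.isoforms[0]))
            wts.append(float(lam[sp][gi]))
        for li, l in enumerate(lnc_loci):
            if not active_in(si, l):
                continue
            tx.append(l.transcript())
            wts.append(float(lnc_weight[li]))
        depth = config.read_depth_per_species[sp]
        if depth < len(tx):
            raise PlacementError(
                f"read depth {depth} for {sp} cannot cover {len(tx)} active transcripts"
            )
        focal_reads = simulate_read_library(
            tx,
            depth,
            seed=int(rng.integers(2**31)),
            weights=wts,
            read_length=config.read_length,
            ensure_each=True,
        )
        if sp == focal or sp == sister:
            reads[sp] = sorted(focal_reads)
        else:
            projected = []
            for r in focal_reads:
                pr = project_or_none(r, sp)
                if pr is not None:
                    projected.append(pr)
            reads[sp] = sorted(projected)

    # ---- pairwise alignments at feature-class rates ----------------------
    rates = config.branch_rates
    alignments: dict[str, list[PairwiseAlignment]] = {
        "locus": [],
        "promoter": [],
        "exon": [],
        "intron": [],
        "AR": [],
    }
    region_rates: dict[str, float] = {}

    def emit(region_id: str, chrom: str, start: int, end: int, rate: float, cls: str) -> None:
        seq1 = focal_seqs[chrom][start:end]
        seq2 = _mutate_sequence(seq1, rate, jc, rng)
        alignments[cls].append(PairwiseAlignment(region_id, seq1, seq2, cls))
        region_rates[region_id] = rate

    for l in lnc_loci:
        cls_rate = rates["conserved_lncRNA"] if l.category == "I" else rates["lineage_lncRNA"]
        prom_rate = (
            rates["promoter_conserved"] if l.category == "I" else rates["promoter_lineage"]
        )
        span = l.span
        emit(l.id, span.chrom, span.start, span.end, cls_rate, "locus")
        tss = l.tss
        if l.strand == "+":
            ps, pe = max(0, tss - 400), tss
        else:
            ps, pe = tss + 1, min(config.chrom_lengths[span.chrom], tss + 401)
        if ps < pe:
            emit(f"{l.id}_prom", span.chrom, ps, pe, prom_rate, "promoter")
    for g in genes:
        exons = g.isoforms[0]
        span = g.span
        for k, (s, e) in enumerate(exons):
            emit(f"{g.id}_ex{k}", g.chrom, s, e, rates["pc_exon"], "exon")
        introns = [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])]
        for k, (s, e) in enumerate(introns):
            emit(f"{g.id}_in{k}", g.chrom, s, e, rates["pc_intron"], "intron")
    for ar_id, iv, _gc in ars:
        emit(ar_id, iv.chrom, iv.start, iv.end, rates["AR"], "AR")

    # ---- sidecars --------------------------------------------------------
    hk_candidates = [
        g.id for g in genes if g.id not in elevated_in and g.id not in lineage_pc_ids
    ]
    hk_idx = rng.choice(len(hk_candidates), size=min(config.n_housekeeping, len(hk_candidates)), replace=False)
    housekeeping = sorted(hk_candidates[int(i)] for i in hk_idx)
    adjacent = [(genes[i].id, genes[i + 1].id) for i in range(len(genes) - 1)
                if genes[i].chrom == genes[i + 1].chrom]
    par_idx = rng.choice(len(adjacent), size=min(config.n_paralog_pairs, len(adjacent)), replace=False)
    paralogs = sorted(adjacent[int(i)] for i in par_idx)
    orthologs = pd.DataFrame(
        {"focal_gene": [g.id for g in genes], "outgroup_gene": ["r" + g.id for g in genes]}
    )

    truth = PlantedTruth(
        lnc_categories={l.id: l.category for l in lnc_loci},
        lnc_loci={
            l.id: {
                "chrom": l.span.chrom,
                "start": l.span.start,
                "end": l.span.end,
                "strand": l.strand,
                "tss": l.tss,
            }
            for l in lnc_loci
        },
        region_rates=region_rates,
        gene_expression={
            g.id: {
                "lambda": {sp: float(lam[sp][gi]) for sp in config.species},
                "elevated_in": elevated_in.get(g.id),
                "housekeeping": g.id in housekeeping,
                "liver": g.id in set(liver_genes),
                "lineage_pc": g.id in lineage_pc_ids,
            }
            for gi, g in enumerate(genes)
        },
        library_scales=dict(exp_cfg.library_scale_per_species),
        territory_fold=config.territory_enrichment_fold,
        indel_purified_fold=config.indel_purified_fold,
    )
    return ScenarioBundle(
        config=config,
        chrom_lengths=dict(config.chrom_lengths),
        outgroup_chrom_lengths=outgroup_chrom_lengths,
        genomes=genomes,
        genes=genes,
        lnc_loci=sorted(lnc_loci, key=lambda l: l.id),
        peaks=peaks,
        reads=reads,
        ars=ars,
        indel_purified=ips,
        maps=maps,
        counts=counts,
        orthologs=orthologs,
        paralogs=[tuple(p) for p in paralogs],
        housekeeping=housekeeping,
        liver_genes=sorted(liver_genes),
        alignments=alignments,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# light-weight study simulators (no genome layout)


def simulate_constraint_panel(
    n_regions: int = 200,
    region_length: int = 20_000,
    d_focal: float = 0.148,
    d_ar: float = 0.164,
    ar_total_length: int = 20_000,
    seed: int = 0,
    rev_params: RevParams = RevParams(),
) -> list[tuple[PairwiseAlignment, PairwiseAlignment]]:
    """Panel of focal-region alignments at ``d_focal`` each paired with a
    pooled matched-AR alignment at ``d_ar`` (the local neutral proxy)."""
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(n_regions):
        reg = evolve_pair(
            region_length, d_focal, rev_params, seed=int(rng.integers(2**31)),
            region_id=f"region{i:04d}", feature_class="locus",
        )
        ar = evolve_pair(
            ar_total_length, d_ar, rev_params, seed=int(rng.integers(2**31)),
            region_id=f"region{i:04d}_AR", feature_class="AR",
        )
        panel.append((reg, ar))
    return panel


def simulate_neighbor_expression(
    n_gene_a_lineage: int = 150,
    n_gene_a_conserved: int = 148,
    n_gene_b: int = 120,
    n_gene_a_prime: int = 89,
    n_housekeeping: int = 230,
    n_background: int = 2000,
    elevation: float = 0.25,
    library_scale_y: float = 1.0,
    baseline_log_mean: float = 3.0,
    baseline_log_sd: float = 1.0,
    between_species_sd: float = 0.30,
    seed: int = 0,
) -> pd.DataFrame:
    """Count-level neighbor-expression study with planted elevation.

    Emits a per-gene table (group, counts in species x and y, constitutive
    length, bearing species) mimicking the focal-vs-outgroup comparison:
    genes A near lineage-specific lncRNAs are elevated by ``elevation`` in
    the lncRNA-bearing species (assigned at random per gene); genes B,
    genes A near conserved lncRNAs, genes A' near lineage-specific
    protein-coding genes and housekeeping genes carry no planted shift. The
    background group fills out the ortholog set used for normalization.
    """
    rng = np.random.default_rng(seed)
    groups = (
        ["gene_A_lineage"] * n_gene_a_lineage
        + ["gene_A_conserved"] * n_gene_a_conserved
        + ["gene_B"] * n_gene_b
        + ["gene_A_prime"] * n_gene_a_prime
        + ["housekeeping"] * n_housekeeping
        + ["background"] * n_background
    )
    n = len(groups)
    lam = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, n))
    noise_x = np.exp(rng.normal(0, between_species_sd, n))
    noise_y = np.exp(rng.normal(0, between_species_sd, n))
    bearing = np.where(rng.random(n) < 0.5, "x", "y")
    lam_x = lam * noise_x
    lam_y = lam * noise_y * library_scale_y
    is_a = np.array([g == "gene_A_lineage" for g in groups])
    lam_x = np.where(is_a & (bearing == "x"), lam_x * (1 + elevation), lam_x)
    lam_y = np.where(is_a & (bearing == "y"), lam_y * (1 + elevation), lam_y)
    lengths = rng.integers(500, 3000, n)
    return pd.DataFrame(
        {
            "gene": [f"g{i:05d}" for i in range(n)],
            "group": groups,
            "count_x": rng.poisson(lam_x),
            "count_y": rng.poisson(lam_y),
            "length_x": lengths,
            "length_y": lengths,
            "bearing": bearing,
        }
    ).set_index("gene")
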