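"""Readers and writers for the standard genomic text formats the pipeline
consumes and emits.

Conventions: BED6/BED12 and narrowPeak are 0-based half-open; GFF3 is
1-based inclusive and converted at this boundary; orthology maps are TSV
``src_chrom src_start src_end tgt_chrom tgt_start orientation`` (0-based
half-open); pairwise alignments are paired FASTA (two consecutive records
per region, equal length).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import PeakRecord, TranscriptModel
from .conservation import OrthologyMap, SyntenicBlock
from .constraint import PairwiseAlignment
from .intervals import GenomicInterval

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------- FASTA
def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sorted(seqs.items())]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------------------ BED
def write_bed6(intervals: Sequence[GenomicInterval], path: str | Path, names=None) -> None:
    rows = []
    for i, iv in enumerate(intervals):
        name = names[i] if names is not None else f"feat{i}"
        rows.append((iv.chrom, iv.start, iv.end, name, 0, iv.strand if iv.strand != "." else "."))
    pd.DataFrame(rows, columns=BED6_COLS).to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> list[GenomicInterval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) > 5 else "."
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), str(strand)))
    return out


def write_bed12(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    rows = []
    for t in transcripts:
        sizes = ",".join(str(e - s) for s, e in t.exons) + ","
        starts = ",".join(str(s - t.start) for s, _ in t.exons) + ","
        rows.append(
            (t.chrom, t.start, t.end, t.id, 0, t.strand, t.start, t.end, "0",
             len(t.exons), sizes, starts)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        chrom, start = str(row[0]), int(row[1])
        name, strand = str(row[3]), str(row[5])
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        exons = tuple((start + o, start + o + z) for o, z in zip(offsets, sizes))
        out.append(TranscriptModel(name, chrom, strand, exons))
    return out


# ------------------------------------------------------------------ narrowPeak
def write_narrowpeak(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    rows = []
    for i, p in enumerate(peaks):
        rows.append(
            (p.interval.chrom, p.interval.start, p.interval.end, f"peak{i}", 0, ".",
             0.0, -1.0, -1.0, p.summit - p.interval.start)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: str | Path) -> list[PeakRecord]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(str(row[0]), int(row[1]), int(row[2]))
        summit = iv.start + int(row[9]) if len(row) > 9 and int(row[9]) >= 0 else (iv.start + iv.end) // 2
        out.append(PeakRecord(iv, summit))
    return out


# ----------------------------------------------------------------------- GFF3
def write_gff3(genes, path: str | Path, source: str = "lncturnover") -> None:
    """Write protein-coding gene models (gene -> mRNA -> exon) as GFF3."""
    lines = ["##gff-version 3"]
    for g in genes:
        span = g.span
        lines.append(
            "\t".join(
                [span.chrom, source, "gene", str(span.start + 1), str(span.end), ".",
                 g.strand, ".", f"ID={g.id};biotype=protein_coding"]
            )
        )
        for ti, exons in enumerate(g.isoforms):
            tid = f"{g.id}.t{ti + 1}"
            lines.append(
                "\t".join(
                    [span.chrom, source, "mRNA", str(exons[0][0] + 1), str(exons[-1][1]), ".",
                     g.strand, ".", f"ID={tid};Parent={g.id}"]
                )
            )
            for k, (s, e) in enumerate(exons):
                lines.append(
                    "\t".join(
                        [span.chrom, source, "exon", str(s + 1), str(e), ".", g.strand, ".",
                         f"ID={tid}.e{k + 1};Parent={tid}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_genes(path: str | Path):
    """Parse gene/mRNA/exon GFF3 into PCGene records (1-based inclusive ->
    0-based half-open)."""
    from .synthetic import PCGene

    genes: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, ftype, start, end, _score, strand, _phase, attrs = line.split("\t")
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype == "gene":
            genes[attr["ID"]] = {"chrom": chrom, "strand": strand, "tx": {}}
        elif ftype == "mRNA":
            tx_parent[attr["ID"]] = attr["Parent"]
            genes[attr["Parent"]]["tx"][attr["ID"]] = []
        elif ftype == "exon":
            gene_id = tx_parent[attr["Parent"]]
            genes[gene_id]["tx"][attr["Parent"]].append((int(start) - 1, int(end)))
    out = []
    for gid in sorted(genes):
        rec = genes[gid]
        isoforms = [tuple(sorted(exons)) for _, exons in sorted(rec["tx"].items())]
        out.append(PCGene(gid, rec["chrom"], rec["strand"], isoforms))
    return out


# -------------------------------------------------------------- orthology map
def write_orthology_map(omap: OrthologyMap, path: str | Path) -> None:
    rows = [
        (b.src_chrom, b.src_start, b.src_end, b.tgt_chrom, b.tgt_start, b.orientation)
        for b in omap.blocks
    ]
    pd.DataFrame(
        rows, columns=["src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start", "orientation"]
    ).to_csv(path, sep="\t", index=False)


def read_orthology_map(path: str | Path) -> OrthologyMap:
    df = pd.read_csv(path, sep="\t")
    blocks = [
        SyntenicBlock(
            str(r.src_chrom), int(r.src_start), int(r.src_end), str(r.tgt_chrom),
            int(r.tgt_start), str(r.orientation),
        )
        for r in df.itertuples(index=False)
    ]
    return OrthologyMap(blocks)


# ----------------------------------------------------------------- alignments
def write_paired_fasta(alignments: Sequence[PairwiseAlignment], path: str | Path) -> None:
    records = []
    for a in alignments:
        records.append(SeqRecord(Seq(a.seq1), id=f"{a.region_id}|sp1", description=a.feature_class))
        records.append(SeqRecord(Seq(a.seq2), id=f"{a.region_id}|sp2", description=a.feature_class))
    SeqIO.write(records, str(path), "fasta")


def read_paired_fasta(path: str | Path) -> list[PairwiseAlignment]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2:
        raise ValueError("paired FASTA must contain an even number of records")
    out = []
    for r1, r2 in zip(records[::2], records[1::2]):
        rid = r1.id.rsplit("|", 1)[0]
        cls = r1.description.split()[-1] if r1.description else "locus"
        if cls not in ("locus", "promoter", "exon", "intron", "AR"):
            cls = "locus"
        out.append(PairwiseAlignment(rid, str(r1.seq).upper(), str(r2.seq).upper(), cls))
    return out


# --------------------------------------------------------------------- bundle
def write_bundle(bundle, outdir: str | Path) -> None:
    """Serialize a ScenarioBundle to its on-disk file set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp in bundle.config.species:
        spdir = outdir / sp
        spdir.mkdir(exist_ok=True)
        write_fasta(bundle.genomes[sp], spdir / "genome.fa")
        write_narrowpeak(bundle.peaks[sp], spdir / "h3k4me3.narrowPeak")
        write_bed6(
            bundle.reads[sp], spdir / "reads.bed",
            names=[f"read{i}" for i in range(len(bundle.reads[sp]))],
        )
    write_gff3(bundle.genes, outdir / "genes.gff3")
    lnc_tx = [l.transcript() for l in bundle.lnc_loci]
    write_bed12(lnc_tx, outdir / "lnc_transcripts.bed12")
    ar_rows = [
        (iv.chrom, iv.start, iv.end, ar_id, gc, ".") for ar_id, iv, gc in bundle.ars
    ]
    pd.DataFrame(ar_rows, columns=BED6_COLS).to_csv(
        outdir / "ancestral_repeats.bed", sep="\t", header=False, index=False
    )
    write_bed6(
        bundle.indel_purified, outdir / "indel_purified.bed",
        names=[f"ips{i}" for i in range(len(bundle.indel_purified))],
    )
    outgroup = bundle.config.species[2]
    write_orthology_map(bundle.maps[outgroup], outdir / "orthology_map.tsv")
    bundle.counts.to_csv(outdir / "counts.tsv", sep="\t")
    bundle.orthologs.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
    pd.DataFrame(bundle.paralogs, columns=["gene1", "gene2"]).to_csv(
        outdir / "paralogs.tsv", sep="\t", index=False
    )
    Path(outdir / "housekeeping.txt").write_text("\n".join(bundle.housekeeping) + "\n")
    Path(outdir / "liver_genes.txt").write_text("\n".join(bundle.liver_genes) + "\n")
    for cls, alns in sorted(bundle.alignments.items()):
        if alns:
            write_paired_fasta(alns, outdir / f"alignments_{cls}.fa")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(bundle.truth.to_dict(), fh, indent=1, sort_keys=True)
    cfg = bundle.config
    cfg_dict = {
        "seed": cfg.seed,
        "species": list(cfg.species),
        "chrom_lengths": dict(cfg.chrom_lengths),
        "n_protein_coding": cfg.n_protein_coding,
        "n_lncRNA_per_category": dict(cfg.n_lncRNA_per_category),
        "read_depth_per_species": dict(cfg.read_depth_per_species),
        "branch_rates": dict(cfg.branch_rates),
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
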