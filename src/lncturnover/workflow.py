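"""End-to-end analyses over a synthetic scenario bundle.

Thin orchestration: each function runs one study stage on a
:class:`~lncturnover.synthetic.ScenarioBundle` by composing the library
modules, and returns plain results that the analysis drivers and the
acceptance checks consume.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .conservation import (
    ConservationCall,
    classify_conservation,
    expression_evidence_at,
    project_interval,
)
from .expression import fold_differences, fpkm_table, tmm_factors
from .intervals import GenomicInterval, IntervalIndex
from .neighbors import (
    EnrichmentResult,
    expression_shift_test,
    neighbor_pairs,
    permutation_enrichment,
)
from .synthetic import ScenarioBundle


def classify_bundle(bundle: ScenarioBundle, mode: str = "strict") -> dict[str, ConservationCall]:
    """Conservation category for every planted lncRNA locus, from the
    bundle's own evidence tracks (peaks + stranded reads per species)."""
    focal, sister, outgroup = bundle.config.species
    peak_idx = {
        sp: IntervalIndex([p.interval for p in bundle.peaks[sp]]) for sp in bundle.config.species
    }
    read_idx = {sp: IntervalIndex(bundle.reads[sp]) for sp in bundle.config.species}
    calls: dict[str, ConservationCall] = {}
    for locus in bundle.lnc_loci:
        span = locus.span
        evidence = []
        for sp in bundle.config.species:
            if sp == focal:
                segments = [span]
            else:
                segments = project_interval(span, bundle.maps[sp])
            evidence.append(
                expression_evidence_at(segments, peak_idx[sp], read_idx[sp], species=sp, mode=mode)
            )
        calls[locus.id] = classify_conservation(locus.id, evidence, mode=mode)
    return calls


def category_recovery(bundle: ScenarioBundle, mode: str = "strict") -> tuple[float, pd.DataFrame]:
    """Fraction of planted categories recovered, plus the per-locus table."""
    calls = classify_bundle(bundle, mode=mode)
    rows = []
    for lid, truth_cat in sorted(bundle.truth.lnc_categories.items()):
        rows.append((lid, truth_cat, calls[lid].category))
    df = pd.DataFrame(rows, columns=["locus", "planted", "called"])
    return float((df.planted == df.called).mean()), df


def territory_enrichment(
    bundle: ScenarioBundle, n_perms: int = 1000, seed: int = 0
) -> EnrichmentResult:
    """Enrichment of focal lncRNA loci in liver-expressed gene territories,
    randomized within the intergenic workspace."""
    from .neighbors import gene_territories

    terr = gene_territories(bundle.gene_features(), bundle.chrom_lengths)
    liver = set(bundle.liver_genes)
    annotation = [iv for gid, iv in sorted(terr.items()) if gid in liver]
    workspace = []
    for chrom, clen in sorted(bundle.chrom_lengths.items()):
        spans = [
            (max(0, g.start - 500), min(clen, g.end + 500))
            for g in bundle.genes
            if g.chrom == chrom
        ]
        from .intervals import subtract_pairs

        for s, e in subtract_pairs([(0, clen)], spans):
            workspace.append(GenomicInterval(chrom, s, e))
    focal_active = [l.span for l in bundle.lnc_loci if l.category in ("I", "II", "III")]
    return permutation_enrichment(focal_active, annotation, workspace, n_perms=n_perms, seed=seed)


def expression_study(
    table: pd.DataFrame,
    assumed_fraction: float = 0.6,
    seed: int = 0,
) -> dict:
    """Between-species expression comparison on a per-gene count table.

    ``table`` needs columns ``group``, ``count_x``, ``count_y``,
    ``length_x``, ``length_y`` and ``bearing`` (which species carries the
    lineage-specific lncRNA for gene-A rows). Returns TMM factors, per-gene
    fold-differences and the per-group shift tests against the housekeeping
    baseline.
    """
    factors = tmm_factors(
        table["count_x"].to_numpy(), table["count_y"].to_numpy(),
        assumed_fraction=assumed_fraction,
    )
    quant = fpkm_table(table, factors)
    fx = dict(zip(quant.index, quant["fpkm_x"]))
    fy = dict(zip(quant.index, quant["fpkm_y"]))
    orientation: dict[str, str] = {}
    for gene, row in quant.iterrows():
        if row["group"] in ("gene_A_lineage", "gene_B"):
            orientation[gene] = row["bearing"]  # lncRNA-bearing species on top
        else:
            orientation[gene] = "random"
    values, _, excluded = fold_differences(fx, fy, orientation, seed=seed)
    folds = pd.Series({v.gene_id: v.value for v in values})
    groups = quant.loc[folds.index, "group"]
    group_folds = {g: folds[groups == g].to_list() for g in sorted(set(groups))}
    baseline = group_folds.get("housekeeping", [])
    tests = expression_shift_test(
        {g: v for g, v in group_folds.items() if g != "housekeeping"}, baseline
    )
    return {
        "factors": factors,
        "folds": folds,
        "groups": groups,
        "tests": tests,
        "baseline_median": float(np.median(baseline)) if baseline else float("nan"),
        "excluded": excluded,
    }


def bundle_neighbor_pairs(bundle: ScenarioBundle):
    """Gene-A/B pairing of the bundle's lncRNA loci with paralog exclusion
    and one-to-one ortholog filtering."""
    paralogs = {frozenset(p) for p in bundle.paralogs}
    orthologs = set(bundle.orthologs["focal_gene"])
    return neighbor_pairs(
        bundle.lnc_features(),
        bundle.gene_features(),
        paralogs=paralogs,
        orthologs=orthologs,
        categories=bundle.truth.lnc_categories,
    )
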