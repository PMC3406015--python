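"""Cross-species gene-expression quantification.

Expression of each gene is measured over its constitutive exons (bases
present in every annotated isoform). Counts in the second species are
adjusted for constitutive-length differences, libraries are normalized by a
trimmed mean of per-gene log ratios (TMM) under the assumption that a
stated fraction of expressed genes (default 60%) is similarly expressed in
the two species, FPKM is computed on the normalized library sizes, and
between-species expression differences are reported as natural-log FPKM
ratios with an explicit orientation rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import intersect_pairs, merge_pairs


@dataclass
class NormalizationFactors:
    species_x: str
    species_y: str
    assumed_fraction: float
    factor: float  # scale applied to species-y library size
    lib_x: float
    lib_y: float

    @property
    def normalized_lib_x(self) -> float:
        return self.lib_x

    @property
    def normalized_lib_y(self) -> float:
        return self.lib_y * self.factor


def constitutive_exons(
    transcript_exons: Sequence[Sequence[tuple[int, int]]],
) -> list[tuple[int, int]]:
    """Genomic bases present in every transcript of a gene, as maximal
    intervals. Raises when the intersection is empty (gene excluded
    downstream)."""
    if not transcript_exons:
        raise ValueError("gene has no transcripts")
    acc = merge_pairs(transcript_exons[0])
    for exons in transcript_exons[1:]:
        acc = intersect_pairs(acc, list(exons))
        if not acc:
            raise ValueError("empty constitutive-exon intersection")
    return acc


def length_adjust_counts(count_other: float, len_focal: int, len_other: int) -> float:
    """Adjust the other species' count to the read total expected if its
    constitutive sequence had the focal species' length (reads per
    nucleotide held fixed)."""
    if len_focal <= 0 or len_other <= 0:
        raise ValueError("constitutive lengths must be positive")
    return count_other * len_focal / len_other


def tmm_factors(
    counts_x: Sequence[float],
    counts_y: Sequence[float],
    lib_x: float | None = None,
    lib_y: float | None = None,
    assumed_fraction: float = 0.6,
    a_trim: float = 0.05,
    species_x: str = "x",
    species_y: str = "y",
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values library scaling between two species.

    M = ln((y/lib_y)/(x/lib_x)) per doubly-expressed gene; the 2*``a_trim``
    most extreme genes by intensity (A) are dropped, then the central
    ``assumed_fraction`` of the remaining genes by M rank is retained and
    the factor is exp(mean M) - the fraction encodes the assumption that
    that share of expressed genes is transcribed at similar levels in both
    species.
    """
    if not (0 < assumed_fraction < 1):
        raise ValueError("assumed_fraction must be in (0, 1)")
    x = np.asarray(counts_x, dtype=float)
    y = np.asarray(counts_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must be paired")
    lx = float(lib_x) if lib_x is not None else float(x.sum())
    ly = float(lib_y) if lib_y is not None else float(y.sum())
    both = (x > 0) & (y > 0)
    if both.sum() < 20:
        raise ValueError(
            f"only {int(both.sum())} doubly-expressed genes; normalization unstable"
        )
    xr = x[both] / lx
    yr = y[both] / ly
    M = np.log(yr / xr)
    A = 0.5 * np.log(yr * xr)
    lo, hi = np.quantile(A, [a_trim, 1 - a_trim])
    keep = (A >= lo) & (A <= hi)
    M = M[keep]
    order = np.argsort(M, kind="stable")
    n = len(M)
    drop = int(np.floor(n * (1 - assumed_fraction) / 2))
    central = M[order][drop : n - drop] if drop > 0 else M[order]
    factor = float(np.exp(central.mean()))
    return NormalizationFactors(species_x, species_y, assumed_fraction, factor, lx, ly)


def fpkm(count: float, length_bp: int, normalized_lib: float) -> float:
    """Fragments per kb of constitutive exon per million normalized mapped
    reads."""
    if length_bp <= 0 or normalized_lib <= 0:
        raise ValueError("length and library size must be positive")
    return 1e9 * count / (length_bp * normalized_lib)


def fpkm_table(
    records: pd.DataFrame,
    factors: NormalizationFactors,
) -> pd.DataFrame:
    """Add FPKM columns to a per-gene table.

    ``records`` needs columns ``count_x``, ``count_y``, ``length_x``,
    ``length_y``; counts in species y are first length-adjusted to the
    species-x constitutive length, then converted with the normalized
    library sizes.
    """
    out = records.copy()
    out["adjusted_count_y"] = [
        length_adjust_counts(c, lf, lo)
        for c, lf, lo in zip(out["count_y"], out["length_x"], out["length_y"])
    ]
    out["fpkm_x"] = [
        fpkm(c, l, factors.normalized_lib_x) for c, l in zip(out["count_x"], out["length_x"])
    ]
    out["fpkm_y"] = [
        fpkm(c, l, factors.normalized_lib_y)
        for c, l in zip(out["adjusted_count_y"], out["length_x"])
    ]
    return out


@dataclass
class FoldDifference:
    gene_id: str
    value: float  # ln(FPKM_X / FPKM_Y)
    orientation: str  # lncRNA_bearing | random_XY


def fold_differences(
    fpkm_x: Mapping[str, float],
    fpkm_y: Mapping[str, float],
    orientation: Mapping[str, str] | str = "random_XY",
    seed: int = 0,
) -> tuple[list[FoldDifference], float, list[str]]:
    """Natural-log between-species fold-differences.

    ``orientation`` gives, per gene, which species is the numerator: ``"x"``
    or ``"y"`` (the lncRNA-bearing species for neighbor analyses), or
    ``"random"`` for the housekeeping/baseline convention where X and Y are
    assigned at random per gene (seeded). A bare string applies one rule to
    all genes. Genes with zero FPKM in either species are excluded and
    returned in the third element.
    """
    rng = np.random.default_rng(seed)
    values: list[FoldDifference] = []
    excluded: list[str] = []
    genes = sorted(set(fpkm_x) & set(fpkm_y))
    if not genes:
        raise ValueError("no genes shared between species tables")
    for g in genes:
        fx, fy = fpkm_x[g], fpkm_y[g]
        rule = orientation if isinstance(orientation, str) else orientation.get(g, "random")
        flip = rng.random() < 0.5  # draw unconditionally to keep the stream aligned
        if fx <= 0 or fy <= 0:
            excluded.append(g)
            continue
        if rule in ("random", "random_XY"):
            value = np.log(fy / fx) if flip else np.log(fx / fy)
            tag = "random_XY"
        elif rule == "x":
            value, tag = np.log(fx / fy), "lncRNA_bearing"
        elif rule == "y":
            value, tag = np.log(fy / fx), "lncRNA_bearing"
        else:
            raise ValueError(f"unknown orientation rule {rule!r}")
        values.append(FoldDifference(g, float(value), tag))
    if not values:
        raise ValueError("all genes excluded (zero FPKM)")
    median = float(np.median([v.value for v in values]))
    return values, median, excluded
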