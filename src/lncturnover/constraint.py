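"""Pairwise substitution-rate estimation under the REV model and
normalization against G+C-matched ancestral repeats (ARs).

The maximum-likelihood distance for a gap-free pairwise alignment is found
by alternating a bounded scalar search over the distance d with quasi-Newton
updates of the six exchangeabilities (empirical base frequencies are held
fixed), until the log-likelihood improves by less than 1e-8. ARs within
500 kb of a focal region, not overlapping any annotated locus and with
similar G+C content provide the local neutral rate d_AR; their alignments
are concatenated and a single pooled d_AR is estimated per focal region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .intervals import GenomicInterval, IntervalIndex
from .revmodel import RevParams, pair_count_matrix, transition_probabilities

FEATURE_CLASSES = ("locus", "promoter", "exon", "intron", "AR")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Gap-free aligned sequence pair for one genomic region."""

    region_id: str
    seq1: str
    seq2: str
    feature_class: str = "locus"

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.seq2):
            raise ValueError("aligned sequences must have equal length")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")

    @property
    def length(self) -> int:
        return len(self.seq1)


@dataclass
class SubstitutionRateEstimate:
    region_id: str
    d: float
    params: RevParams
    aligned_length: int
    log_likelihood: float
    flagged_short: bool = False


@dataclass
class ARMatchSet:
    focal_region_id: str
    ar_ids: list[str]
    pooled_d_ar: float | None
    pooled_length: int
    gc_focal: float
    gc_ars: list[float] = field(default_factory=list)

    @property
    def unnormalizable(self) -> bool:
        return self.pooled_d_ar is None


def _neg_loglik(N: np.ndarray, pi: np.ndarray, s: np.ndarray, d: float) -> float:
    params = RevParams(tuple(s), tuple(pi))
    P = transition_probabilities(params, d)
    with np.errstate(divide="ignore"):
        logjoint = np.log(np.clip(pi[:, None] * P, 1e-300, None))
    return -float(np.sum(N * logjoint))


def estimate_substitution_rate(
    alignment: PairwiseAlignment,
    min_length: int = 50,
    tol: float = 1e-8,
    max_iter: int = 60,
) -> SubstitutionRateEstimate:
    """Maximum-likelihood REV distance for a gap-free pairwise alignment.

    Empirical base frequencies are taken from the pooled composition of the
    two sequences; the distance and the six exchangeabilities are jointly
    optimized. Alignments shorter than ``min_length`` are estimated anyway
    but flagged (summaries exclude them). Non-ACGT columns are dropped with
    a warning.
    """
    N, dropped = pair_count_matrix(alignment.seq1, alignment.seq2)
    if dropped:
        warnings.warn(
            f"{alignment.region_id}: dropped {dropped} non-ACGT columns", stacklevel=2
        )
    total = N.sum()
    if total == 0:
        raise ValueError(f"{alignment.region_id}: no usable aligned columns")
    flagged = total < min_length
    pi = (N.sum(axis=1) + N.sum(axis=0)) / (2 * total)
    pi = np.clip(pi, 1e-6, None)
    pi /= pi.sum()

    n_diff = total - np.trace(N)
    if n_diff == 0:
        params = RevParams((1.0,) * 6, tuple(pi))
        ll = -_neg_loglik(N, pi, np.ones(6), 0.0)
        return SubstitutionRateEstimate(alignment.region_id, 0.0, params, int(total), ll, flagged)

    log_s = np.zeros(6)
    p_obs = n_diff / total
    d = max(-0.75 * np.log1p(-min(p_obs, 0.74) * 4 / 3), 1e-6)
    prev = np.inf
    for _ in range(max_iter):
        res = optimize.minimize_scalar(
            lambda x: _neg_loglik(N, pi, np.exp(log_s), x),
            bounds=(1e-9, 10.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        d = float(res.x)

        def f(ls: np.ndarray) -> float:
            # pin the GT exchangeability at 1 to remove the scale redundancy
            full = np.append(ls, 0.0)
            return _neg_loglik(N, pi, np.exp(full), d)

        res2 = optimize.minimize(f, log_s[:5], method="L-BFGS-B")
        log_s = np.append(res2.x, 0.0)
        cur = float(res2.fun)
        if prev - cur < tol:
            prev = cur
            break
        prev = cur
    params = RevParams(tuple(np.exp(log_s)), tuple(pi))
    return SubstitutionRateEstimate(alignment.region_id, d, params, int(total), -prev, flagged)


def match_ancestral_repeats(
    focal_region: GenomicInterval,
    focal_gc: float,
    ars: Sequence[tuple[str, GenomicInterval, float]],
    annotated_loci: Sequence[GenomicInterval],
    ar_alignments: Mapping[str, PairwiseAlignment] | None = None,
    max_dist: int = 500_000,
    gc_tol: float = 0.05,
    min_length: int = 50,
    focal_id: str = "",
) -> ARMatchSet:
    """Select ARs usable to normalize a focal region's substitution rate.

    ``ars`` is a sequence of ``(ar_id, interval, gc_fraction)``. Qualifying
    ARs lie on the focal chromosome within ``max_dist`` bp of the focal
    envelope, overlap no annotated locus, and have G+C within ``gc_tol`` of
    the focal region. When ``ar_alignments`` is given the selected AR
    alignments are concatenated and a single pooled d_AR is estimated.
    """
    locus_index = IntervalIndex(list(annotated_loci))
    chosen: list[tuple[str, float]] = []
    for ar_id, iv, gc in ars:
        if iv.chrom != focal_region.chrom:
            continue
        if iv.distance_to(focal_region) >= max_dist:
            continue
        if locus_index.any_overlap(iv):
            continue
        if abs(gc - focal_gc) > gc_tol:
            continue
        chosen.append((ar_id, gc))
    if not chosen:
        return ARMatchSet(focal_id, [], None, 0, focal_gc)
    ar_ids = [a for a, _ in chosen]
    gcs = [g for _, g in chosen]
    pooled_d = None
    pooled_len = 0
    if ar_alignments is not None:
        seq1 = "".join(ar_alignments[a].seq1 for a in ar_ids if a in ar_alignments)
        seq2 = "".join(ar_alignments[a].seq2 for a in ar_ids if a in ar_alignments)
        if seq1:
            est = estimate_substitution_rate(
                PairwiseAlignment("pooled_AR", seq1, seq2, "AR"), min_length=min_length
            )
            pooled_d = est.d
            pooled_len = est.aligned_length
    return ARMatchSet(focal_id, ar_ids, pooled_d, pooled_len, focal_gc, gcs)


@dataclass
class ConstraintSummary:
    ratios: dict[str, dict[str, float]]  # group -> region_id -> d/d_AR
    group_medians: dict[str, float]
    vs_ar_tests: dict[str, tuple[float, float] | None]  # group -> (U, p)
    between_group_tests: dict[tuple[str, str], tuple[float, float] | None]
    notices: list[str] = field(default_factory=list)


def normalized_rate_summary(
    estimates: Mapping[str, SubstitutionRateEstimate],
    ar_rates: Mapping[str, float],
    grouping: Mapping[str, str],
) -> ConstraintSummary:
    """Per-region d/d_AR ratios, per-group medians and two-tailed
    Mann-Whitney comparisons.

    ``ar_rates`` maps region id to its pooled matched-AR rate; regions
    without one (unnormalizable) or with flagged-short alignments are left
    out of the summaries. Tests: (a) each group's raw rates against its
    matched AR rates, (b) every group pair on the normalized ratios.
    """
    ratios: dict[str, dict[str, float]] = {}
    raw: dict[str, list[float]] = {}
    ar_vals: dict[str, list[float]] = {}
    notices: list[str] = []
    for rid, est in estimates.items():
        group = grouping.get(rid)
        if group is None:
            continue
        if est.flagged_short:
            notices.append(f"{rid}: alignment below length floor, excluded")
            continue
        d_ar = ar_rates.get(rid)
        if d_ar is None:
            notices.append(f"{rid}: no matched AR, excluded")
            continue
        if d_ar <= 0:
            notices.append(f"{rid}: zero AR rate, excluded")
            continue
        ratios.setdefault(group, {})[rid] = est.d / d_ar
        raw.setdefault(group, []).append(est.d)
        ar_vals.setdefault(group, []).append(d_ar)
    medians = {g: float(np.median(list(r.values()))) for g, r in ratios.items()}
    vs_ar: dict[str, tuple[float, float] | None] = {}
    for g, vals in raw.items():
        if len(vals) < 2:
            vs_ar[g] = None
            notices.append(f"group {g}: fewer than 2 regions, rates-vs-AR test skipped")
            continue
        u, p = stats.mannwhitneyu(vals, ar_vals[g], alternative="two-sided")
        vs_ar[g] = (float(u), float(p))
    between: dict[tuple[str, str], tuple[float, float] | None] = {}
    groups = sorted(ratios)
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            r1 = list(ratios[g1].values())
            r2 = list(ratios[g2].values())
            if len(r1) < 2 or len(r2) < 2:
                between[(g1, g2)] = None
                notices.append(f"groups {g1}/{g2}: too few regions, test skipped")
                continue
            u, p = stats.mannwhitneyu(r1, r2, alternative="two-sided")
            between[(g1, g2)] = (float(u), float(p))
    return ConstraintSummary(ratios, medians, vs_ar, between, notices)
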