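"""Library-size equalization across species.

To separate sequencing-depth effects from biology, the larger RNA libraries
are repeatedly subsampled (without replacement) to the size of the smallest
library, transfrags are re-assembled and re-filtered, and the number of
full-depth lncRNA loci recovered by the re-created library is counted per
replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotate import PeakRecord, TranscriptModel, assemble_transfrags, tss_supported_transcripts
from .intervals import GenomicInterval, IntervalIndex


@dataclass
class DownsampleSummary:
    species: str
    target_size: int
    replicate_counts: list[int]
    mean: float
    sd: float


def subsample_library(
    reads: Sequence[GenomicInterval], n: int, seed: int
) -> list[GenomicInterval]:
    """Exactly ``n`` distinct reads drawn without replacement, deterministic
    for a given seed."""
    if not (0 <= n <= len(reads)):
        raise ValueError(f"cannot draw {n} reads from a library of {len(reads)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[int(i)] for i in idx]


def downsampled_locus_counts(
    reads: Sequence[GenomicInterval],
    target_size: int,
    full_depth_loci: Sequence[GenomicInterval],
    peaks: Sequence[PeakRecord],
    species: str = "",
    replicates: int = 10,
    seed: int = 0,
    min_gap: int = 50,
    min_length: int = 200,
) -> DownsampleSummary:
    """Locus recovery at equalized depth.

    Per replicate the library is subsampled to ``target_size`` reads,
    transfrags are re-assembled and length/TSS-filtered against the fixed
    peak set (chromatin libraries are not downsampled), and the count of
    full-depth lncRNA loci overlapped (>=1 bp) by a re-created transcript is
    recorded. Mean and sample standard deviation (n-1) are reported.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    counts = []
    for r in range(replicates):
        sub = subsample_library(reads, target_size, seed=seed + r)
        tfrags = assemble_transfrags(sub, min_gap=min_gap, min_length=1)
        kept = tss_supported_transcripts(tfrags, peaks, min_length=min_length)
        index = IntervalIndex([t.span for t in kept])
        counts.append(
            sum(1 for locus in full_depth_loci if index.any_overlap(locus))
        )
    arr = np.array(counts, dtype=float)
    sd = float(arr.std(ddof=1)) if replicates > 1 else 0.0
    return DownsampleSummary(species, target_size, counts, float(arr.mean()), sd)
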