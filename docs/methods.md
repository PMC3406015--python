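# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic testbed does and does not show
about real data.

## Study design emulated by the generator

The scenario generator (`lncturnover.synthetic`) emulates a three-taxon
liver transcriptome comparison: a focal mouse taxon and a closely related
sister taxon annotated on the same assembly (their "equivalent positions"
are the identity map), and an outgroup rat-like genome related through
co-linear syntenic blocks with per-block offsets and an optional strand
flip. Each lncRNA locus is planted in one of five transcriptional
conservation categories — I (expressed in all three), II (both mouse taxa),
III (focal only), IV (sister only), V (outgroup only) — and the bundle
emits, per species, exactly the evidence that category implies: an H3K4me3
peak over the (projected) TSS and stranded reads over the (projected)
transcript, for the species in which the locus is transcribed and for no
other.

Default conditions (all exposed on `ScenarioConfig`):

- genome: 2 chromosomes, 3.2 Mb total, uniform base composition at G+C
  0.44 (midpoint of the configured 0.40–0.48 range);
- 300 protein-coding genes (2–5 exons, ~1.5 kb of exon per gene, 1–2
  isoforms) and 10 lncRNA loci per category (1–2 exons, 0.6–1.4 kb
  transcripts, introns 100–250 bp);
- read depths 60 000 / 30 000 / 50 000 (focal / sister / outgroup),
  single-end stranded 36-bp reads confined to exons; the sister library is
  smallest by design so the depth-equalization stage has a target;
- H3K4me3 peaks are 1-kb domains centred on the TSS (promoter-mark
  enrichment is kilobase-scale in vivo; the width also gives the predicted
  5′ ends of sparsely covered transfrags realistic slack against the
  TSS-support rule);
- 150 ancestral repeats (ARs) of 300–600 bp placed in intergenic space,
  with G+C computed from the emitted sequence;
- branch rates (substitutions/site to the outgroup) per feature class:
  conserved lncRNA loci 0.148, lineage-specific loci 0.164, protein-coding
  exons 0.079, introns 0.162, conserved promoters 0.128, lineage promoters
  0.148, ARs 0.164 — the neutral AR rate anchors the scale and conserved
  loci are constrained relative to it by construction;
- per-gene expression: shared log-normal mean (ln-mean 3, ln-sd 1),
  independent per-species log-normal noise of sd 0.30 (so a
  between-species log fold-difference has sd ≈ 0.42, which reproduces a
  housekeeping-baseline |median| near 0.02), Poisson counts;
- a +25% expression elevation planted on the focal-species mean of the
  gene nearest (envelope distance) to each lineage-specific lncRNA locus
  (sister/outgroup means for categories IV/V respectively);
- lncRNA loci placed so that their nucleotide overlap with liver-expressed
  gene territories is 1.6× the randomization null (below).

### Planted signals are calibrated against the estimator's own null

Two plantings deserve explanation because naive versions are not
recoverable:

**Coding potential.** The coding screen scores the longest forward-strand
ORF of a transcript against k dinucleotide-preserving shuffles
(Altschul–Erickson), labelling it noncoding iff the z-score is negative or
no ORF exists. A uniformly random sequence scores z ≈ 0 with an
essentially random sign, and inserting stop codons does not help for long:
the shuffle null preserves composition, so it adapts to stop enrichment.
Planted lncRNA spans are therefore generated ATG-free (every ATG mutated
to ACG; replacing the middle base cannot create a new start codon). The
longest ORF of the span — and of every genomic substring an assembler
might recover, introns included — is exactly zero, while shuffles recreate
ATGs, keeping the score negative. Protein-coding mRNAs conversely carry a
single ORF spanning nearly the whole transcript. This is a deliberately
sharp caricature: real noncoding transcripts contain spurious ORFs, and
passing the recovery tests shows the plumbing and the sign convention are
right, not that the statistic separates real lncRNAs from real mRNAs.

**Territory enrichment.** The permutation test re-places each segment
uniformly among the positions where it fits inside a single workspace
interval on its own chromosome. That placement law is not uniform over
base pairs — placements taper near interval edges, exactly where gene
territories change hands — so planting "1.6-fold" against the raw
base-pair share of liver territories over-shoots. The generator instead
computes the expected liver overlap of the null placement law exactly
(prefix sums over the workspace) and allocates fold × that share of lncRNA
nucleotides to liver territories, stratified per category and length-aware,
with liver-gene counts balanced per chromosome. Realized fold across seeds
is 1.6 ± ≈0.05.

## Annotation

Coordinates are 0-based half-open internally; GFF3 is converted at the I/O
boundary. Transfrag assembly merges stranded reads whose gaps are ≤
`min_gap` (default 50 bp for dense data; the analysis drivers use 250 bp,
appropriate for the sparse read depths simulated here) and is deliberately
single-exon — a desk-scale stand-in for a spliced assembler, which is why
planted lncRNA introns are short enough to be bridged. The TSS-support rule
requires a peak to contain the TSS coordinate itself, not merely overlap
the transcript. Genic context is strand-agnostic (≥1 bp overlap with a
gene span); antisense transcription is handled by its own rule chain:
(i) same-strand match to an annotated transcript, (ii) no peak at the 5′
end independent of the host gene's TSS, (iii) no 5′ peak at all, (iv) a
manual artifact list (never auto-applied). Locus clustering merges
transcripts whose spans overlap (exonic or intronic bases); a locus is an
intergenic lncRNA locus iff every member is intergenic and noncoding.
Loci with intragenic members are protein-coding when any member overlaps
an annotated gene on the same strand (or an intergenic member looks
coding), else `intragenic_other` — the annotation-driven remainder class.

Promoters are `[tss−400, tss)` on + and `[tss+1, tss+401)` on −, truncated
at chromosome edges and flagged; a promoter of zero length (TSS at
position 0) is returned as `None` with the flag set.

## Conservation classification

Expression evidence at a projected region is peak overlap ≥1 bp
(strandless) AND ≥1 overlapping read matching the projected strand;
`reads_only` mode drops the peak requirement (used when a species lacks
chromatin data). The category truth table is exactly the five patterns
above; the evidence vector (focal+outgroup without sister, or all-false
for a locus that was annotated as expressed in the focal species) raises —
descent cannot produce those patterns in this design, and silently
classifying them would hide upstream errors. Loci lacking an outgroup
ortholog are excluded from turnover statistics (sequence turnover, not
transcriptional turnover). Partial projections are classified on the
projected portion and flagged.

## Substitution rates and constraint

The REV/GTR rate matrix is Q<sub>ij</sub> = s<sub>ij</sub>π<sub>j</sub>,
scaled to one expected substitution per site per unit distance. For a
gap-free pairwise alignment the distance is maximised by alternating a
bounded scalar search over d ∈ [10⁻⁹, 10] with L-BFGS-B updates of the six
exchangeabilities (GT pinned at 1; base frequencies fixed at the pooled
empirical composition), to 10⁻⁸ on the log-likelihood. Transition
probabilities come from the symmetric eigendecomposition
B = D<sup>1/2</sup>QD<sup>−1/2</sup>. With symmetric data the optimum
reduces to the Jukes–Cantor closed form (verified to 10⁻⁴); identical
sequences short-circuit to d = 0. Alignments shorter than 50 bp are
estimated but flagged and excluded from summaries; non-ACGT columns are
dropped with a warning.

AR normalisation selects repeats within 500 kb of the focal envelope, not
overlapping any annotated locus, with |ΔGC| ≤ 0.05 (the G+C tolerance is a
package choice; "similar G+C" is not quantified in the field's usage), and
estimates one pooled d<sub>AR</sub> from the concatenated AR alignments —
short repeats make per-AR likelihoods unstable, and pooling matches the
one-number-per-region normalisation. Regions with no qualifying AR are
flagged unnormalizable and excluded.

Simulation counterpart: `evolve_pair` draws the first sequence from the
stationary composition and mutates it across distance d; by
time-reversibility the pair has the correct two-taxon joint law. Bundle
alignments are generated by mutating the focal genome substring at the
feature-class rate — they play the role of precomputed whole-genome
pairwise alignments and are not re-derivable from the emitted outgroup
genome sequence, which is an independent realisation.

## Expression and normalisation

TMM is reimplemented rather than delegated because the
fraction-of-similar-genes assumption (default 0.6) is the analysis's
stated knob: per doubly-expressed gene, M = ln((y/L<sub>y</sub>)/(x/L<sub>x</sub>));
the 5% extreme-intensity (A) tails are dropped, the central
`assumed_fraction` of genes by M rank is retained, and the factor
exp(mean M) scales the second library size. Cross-checks: a pure 3× depth
difference is recovered to <0.1%; factors under assumed fractions 0.5 and
0.7 agree within 10%.

FPKM = 10⁹ · count / (constitutive length × normalised library size), with
the second species' count first adjusted to the focal constitutive length
(reads per nucleotide held fixed). Fold-differences are natural-log FPKM
ratios — the ≈25% elevation corresponds to ln 1.25 ≈ 0.223, which is why
the natural log (not log2) is the right scale for the printed medians.
Genes with zero FPKM in either species are excluded rather than
pseudocounted (no arbitrary constant; the exclusion list is returned).
Orientation: the lncRNA-bearing species is the numerator for gene-A/B
groups; X/Y are assigned at random per gene (seeded) for housekeeping and
conserved-class baselines, whose expectation is therefore zero by
symmetry.

## Neighborhood statistics

Gene A is the closest gene by envelope (gap) distance with a leftmost
deterministic tie-break; TSS-to-TSS distance is reported alongside (both
conventions are exposed because nearest-gene selection and the distance
statistic serve different sentences in practice). A gene B annotated as a
paralog of gene A is replaced by the next qualifying gene; pairs whose A
or B lacks a one-to-one ortholog are dropped with a recorded reason.
Orientation: same strand → tandem; otherwise order the two TSSs — left
element on − and right on + diverge, the mirror converges. Territories put
boundaries at midpoints between adjacent gene envelopes, chromosome ends
closing the terminal territories.

The permutation engine counts per-segment overlap (not the union), so the
statistic is additive and the null is exchangeable segment by segment; the
empirical p is (1 + #{perm ≥ obs})/(n+1) in the observed direction
(mirrored for depletion), and an always-upper-tail `p_enrichment` is also
reported — the directional p is conservative at conventional levels but
concentrates below ~0.6 under the null, so calibration checks use the
upper-tail form. Optional G+C matching restricts placements to workspace
windows in the same G+C decile; the synthetic genome is compositionally
homogeneous, so the analyses here run unmatched.

## Problem sizes

The shipped drivers and checks use: the default 3.2-Mb scenario (50 lncRNA
loci, 300 genes); 200 regions × 20 kb (plus pooled ARs of equal length)
for constraint recovery and 100 × 10 kb for the neutral lineage-class
contrast; 50-seed replicate studies for the housekeeping baseline and
neighbor-elevation aggregates; 1000 permutations for territory
enrichment. These sizes put the Monte-Carlo error of each recovered
quantity well inside its interpretation window (e.g. SE of the median
d/d<sub>AR</sub> ≈ 0.002).

## Limitations

- The generator plants single-exon-style evidence and gap-free alignments:
  no indel evolution, no sequencing error, no quality scores, no spliced
  multi-exon assembly. Indel-purified segments are emitted as a track, not
  simulated mechanistically.
- Synthetic lncRNA sequence is ATG-free; real coding-potential
  discrimination is far harder, and the screen here preserves only the
  sign convention of coding-potential classifiers.
- The sister taxon shares the focal assembly; assembly-quality asymmetries
  between real genomes are not modelled.
- Rate estimation is pairwise, single-distance, without among-site rate
  variation (no gamma) or codon structure.
- The neighbor-elevation association is planted as a causal effect for
  recovery testing; the statistics on real data would support association
  only.
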