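# lncturnover

Comparative analysis of long noncoding RNA (lncRNA) transcription across
closely related rodent genomes: annotation of liver-expressed intergenic
lncRNA loci from stranded RNA-seq plus H3K4me3 ChIP-seq, classification of
cross-species transcriptional conservation, estimation of nucleotide
constraint against ancestral repeats, and association of lineage-specific
lncRNA transcription with the expression of neighboring protein-coding
genes.

The package is organised as an analysis project: every computation lives in
the importable library under `src/lncturnover/`, the numbered scripts under
`analysis/` are thin narrative drivers, and a synthetic multi-species
scenario generator with planted truth makes every stage testable without
the original sequencing data.

## The analyses

**Annotation.** Transcript fragments are assembled from stranded reads,
filtered to ≥200 nt with an H3K4me3 peak over the predicted TSS, split into
intergenic/intragenic by ≥1 bp overlap with protein-coding annotation, and
screened for coding potential (z-score of the longest-ORF length against
dinucleotide-preserving shuffles; noncoding iff z < 0). Transcribed loci
are transitive clusters of transcripts sharing exonic or intronic bases; a
locus whose members are all intergenic and noncoding is an intergenic
lncRNA locus. Promoters are the 400 bp upstream of the TSS.

**Conservation.** A locus is projected through co-linear syntenic blocks to
each other species and called expressed there when the orthologous position
carries an overlapping peak (≥1 bp) and ≥1 strand-matched read. The
three-species evidence vector yields categories I (all three rodents),
II (both mouse taxa), III (focal only), IV (sister only), V (outgroup
only); loci without an aligned outgroup ortholog are excluded. Turnover
differences between lncRNA and protein-coding loci are tested with
two-tailed Fisher exact tests.

**Constraint.** Pairwise substitution rates *d* are maximum-likelihood
distances under the general time-reversible (REV/GTR) model — empirical
base frequencies, exchangeabilities and *d* jointly optimised. Each
region's rate is normalised by the pooled rate *d*<sub>AR</sub> of
non-overlapping ancestral repeats within 500 kb with similar G+C content
(|ΔGC| ≤ 0.05): *d*/*d*<sub>AR</sub> < 1 indicates purifying selection.
Groups are compared with two-tailed Mann–Whitney tests.

**Expression.** Genes are quantified over constitutive exons (bases in
every isoform), counts length-adjusted between species, libraries
normalised by a trimmed mean of per-gene log ratios (TMM) under the
assumption that 60% of expressed genes are similarly expressed, and
converted to FPKM on the normalised library sizes. Between-species
differences are natural-log FPKM ratios, oriented toward the lncRNA-bearing
species for neighbor analyses and randomly for the housekeeping baseline.

**Neighborhood.** Each lncRNA locus is paired with its closest
protein-coding gene A and next-closest non-paralogous gene B (one-to-one
orthologs only), with tandem/divergent/convergent orientation classes.
Overlap enrichments (e.g. lncRNA loci in liver-expressed gene territories)
use a length-preserving, per-chromosome permutation null with empirical
p = (1 + #{perm ≥ obs})/(n+1). Expression shifts of each neighbor group are
tested against the housekeeping baseline with two-tailed Mann–Whitney
tests.

## Worked example

Generate the default synthetic study (3 species, 300 protein-coding genes,
50 lncRNA loci across categories I–V) and run the conservation and
neighborhood stages:

```bash
python analysis/01_simulate_scenario.py --seed 1
python analysis/04_classify_conservation.py --seed 1
python analysis/07_neighbor_effects.py --seed 1
```

prints, among other things:

```
category recovery: 100.0% of 50 loci
...
expression shifts vs housekeeping baseline (ln fold-difference):
  gene_A_lineage: n=150, median=+0.261, p=0.00741
  gene_B: n=119, median=+0.006, p=0.796
...
liver-territory enrichment: fold = 1.54, p = 0.011 (1000 permutations)
```

Reading: all 50 planted conservation categories are recovered from the
bundle's peaks and reads; genes whose nearest lncRNA is lineage-specific
show the planted ≈25% expression elevation (ln 1.25 ≈ 0.22) relative to the
housekeeping baseline while the next-nearest genes B do not; and lncRNA
loci are enriched in liver-expressed gene territories close to the planted
1.6-fold. The constraint driver
(`analysis/05_estimate_constraint.py`) reports median *d* = 0.148 for
conserved-class loci against *d*<sub>AR</sub> = 0.164
(*d*/*d*<sub>AR</sub> = 0.901), with lineage-class loci at the neutral
ratio ≈ 1.

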