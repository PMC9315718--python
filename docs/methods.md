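# Methods

## Data model

A two-bulk SNP table holds, per biallelic SNP, the chromosome, 1-based
position, reference and alternative alleles, and per-bulk allele depths
(AD), total depth (DP) and genotype quality (GQ), in the GATK
`VariantsToTable` column convention.  Sites with indels, symbolic or
multiple alternative alleles, or a missing genotype/AD in either bulk
are dropped at import (counts logged): all four statistics are defined
on a single ref/alt pair observed in both bulks.  Missing GQ is stored
as 0 so a GQ filter removes rather than silently keeps such records.
AD_REF + AD_ALT may be less than DP (DP counts reads that are
uninformative for the two alleles); depth filters therefore act on DP
while the "informative" rule acts on the AD sum.

Filtering rules are non-strict at the boundary (a record with
GQ = min_gq passes).  Each removed SNP is attributed to the first rule
it fails in the fixed order: informative, total depth, per-bulk depth,
depth difference, GQ — making per-rule counts deterministic.

## Statistics

ΔSNP-index is signed (high − low); ED and G are unsigned.  ED's
exponent is exposed (default 1) because published pipelines disagree
between raw ED and ED⁴/ED⁵.  G uses the 0·ln 0 = 0 convention; a table
with an empty allele column contributes 0 from those cells.

The empirical-Bayes posterior is the probability that a SNP is
completely linked to the causal locus given its reads, under:

- prior π = linkage_span / genome_length.  linkage_span (default 1 Mb)
  is the span treated as completely linked; it is a documented, tunable
  approximation, not an estimate.
- unlinked: bulk alt-chromosome count m_b ~ Binomial(2n_b, ½)
  independently per bulk;
- completely linked: the selected (high) bulk is fixed at m = 2n or
  m = 0 — both allele orientations averaged with weight ½ — and the
  contrasting bulk draws m ~ Binomial(2n, f), f = ½ for an unselected
  bulk or ⅓ for a phenotypically wildtype (dominant-class) F2 bulk,
  mirrored to 1 − f for the opposite orientation;
- reads: alt_b | m_b ~ Binomial(r_b + a_b, m_b/2n_b).

All marginal likelihoods are accumulated in log space (logsumexp over
the composition grid); the per-bulk factorisation makes evaluation
O(n) per bulk, and the test suite pins it against an exhaustive
probability-space double sum over all (m_high, m_low) pairs.  At zero
depth the posterior equals the prior.

Note the two meanings of "contrasted" in this package: for the Bayes
model it is a phenotypically wildtype F2 bulk (frequency ⅓); for the
simulator's `low_bulk` option it is a bulk selected for the opposite
homozygote (frequency r).  Both designs occur in practice; the
docstrings state which is which.

## Smoothing and significance

Tricube Nadaraya–Watson smoothing: `width` is the FULL window (e.g.
5 Mb); the kernel half-width is h = width/2 centred on the focal SNP,
w = (1 − (d/h)³)³, never crossing chromosome boundaries.  The focal SNP
always contributes weight 1, so smoothed values are finite convex
combinations of raw values, and smoothing is linear.  Windows are
physical distance (bp), not genetic distance.  The row-normalised
weight matrix depends only on positions and is cached as a sparse
matrix, so permutation re-smoothing is a matrix–vector product.

Quantile thresholds use the linear-interpolation empirical quantile
(the k/(n−1) order-statistic convention; values 1..100 at q = 0.95 give
95.05).

The permutation test shuffles raw values uniformly across all SNP
positions genome-wide — destroying linkage while preserving both the
marginal value distribution and the SNP spacing — re-smooths with the
cached weights, and pools every permuted smoothed value into one null
sample.  p_i = (1 + #{null ≥ smoothed_i}) / (1 + |null|); the +1 keeps
p > 0.  "≥" is counted with a 1e-9 relative slack because re-smoothing
a permutation of identical values differs from the observed value by
rounding alone.  Value shuffling (rather than bulk-label or count
resampling) is used because significance is defined on the smoothed
values and value shuffling needs no recomputation of per-SNP
statistics; count-level resampling is future work.  Pooled p-values are
marginally calibrated as a mixture across positions: edge SNPs have
wider smoothed distributions than interior ones, so per-position
calibration is approximate while the aggregate distribution is uniform
under the null.  For signed statistics (ΔSNP) the comparison is done on
|smoothed| when requested.

## Candidate regions

A SNP is significant when its smoothed value reaches the quantile
threshold (computed on |smoothed| for signed statistics) or its
permutation p-value falls below α.  Region bounds are the first and
last significant SNP positions — not window-extended — so
length = (end − start)/1e6 Mb.  Runs of significant SNPs whose
consecutive gaps exceed `merge_gap` (default: the window width) are
split; regions with fewer than `min_snps` (default 10) significant
members are discarded.  Member counts include only significant SNPs.
Tightening the threshold always yields regions nested inside the looser
call set.

## Simulator

`simulate_bulks` emulates an F2 or RIL two-bulk experiment: SNP
positions uniform per chromosome (plus a SNP at the causal position —
the causal variant itself segregates between the parents); physical
distance maps to recombination fraction r by the Haldane function at a
uniform rate (default 1 cM/Mb); the high bulk is selected homozygous at
the causal locus so a marker's alt-chromosome frequency is 1 − r
(F2: m ~ Binomial(2n, 1 − r); RIL: line counts ~ Binomial(n, 1 − R)
with R = 2r/(1 + 2r)); the low bulk is unselected (frequency ½) or
contrasted (frequency r).  Depth is Poisson (default mean 50; optional
gamma-Poisson overdispersion); alt reads are Binomial(depth,
composition frequency).  Defaults — 30 individuals per bulk, mean depth
50, 2000 SNPs on one 50 Mb chromosome, causal at 25 Mb — describe a
mid-sized plant-genetics bulk experiment.

What the simulator does **not** emulate: linkage disequilibrium between
markers given a shared set of sampled individuals (composition is drawn
independently per SNP, so adjacent markers are less correlated than in
a real bulk), genotyping error, mapping bias, duplicated or repetitive
regions, multi-QTL architectures and selection-intensity variation.
Passing tests therefore demonstrate correctness of the statistics and
machinery under the stated sampling model, not robustness to artefacts
of real short-read data.

A single simulated chromosome carrying the causal locus is useful for
statistic-level checks, but a quantile threshold is a *genome-wide*
outlier criterion: on an all-signal chromosome the 99% quantile flags
only the top 1% of SNPs near the smoothed apex, whose position wanders
roughly ±1 Mb at the default design.  Reliable coverage of the causal
base by a called region therefore requires a multi-chromosome genome
in which most SNPs are unlinked — the setting the pipeline is built
for, exercised in `tests/test_pipeline.py`.

## Numerical and interface choices

- Tables and tracks are plain pandas DataFrames with documented
  columns; all intermediate artifacts are TSVs so CLI stages compose.
- Sorting is lexicographic by (CHROM, POS) everywhere, making every
  output deterministic given the input.
- Gene extents from GTF are the min/max over all features sharing a
  `gene_id` (correct both for explicit `gene` rows and exon-only
  files); gene–region overlap is closed-interval, any-overlap, strand
  ignored.  The differential-expression table is an input (gene id,
  log2 fold change, FDR) joined by gene id; expression analysis itself
  is out of scope.
- Plots are one panel per chromosome, x in Mb; threshold lines are red
  (quantile) and blue (p-value); tests assert structure (panel/line
  counts), not pixels.

## Problem sizes

The test suite and `scripts/acceptance.py` run at desk scale: 1000
random tables for statistic oracles, 50-SNP tracks for smoothing
oracles, 200 SNPs × 200 permutations × 50 seeds for permutation
calibration (geometry chosen sparse — about two SNPs per window — so
the Kolmogorov–Smirnov uniformity check is applied where its
independence assumption approximately holds), and 10–20 simulated
replicates of the default study for end-to-end checks.

## Limitations

- No QTL-seq-style confidence bands on ΔSNP-index, no FDR machinery
  (raw p-value thresholds only), no multi-allelic sites, no genetic-map
  windows, at most one causal locus per simulation.
- The empirical-Bayes model assumes the high bulk is perfectly selected
  (homozygous at the causal locus); misphenotyping is not modelled.
- Permutation p-values assume exchangeability of raw values across
  positions; depth gradients along the genome would violate this.
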