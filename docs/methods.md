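# Methods

`braintx` re-implements, as a tested library, the bespoke analytical
procedures of a multi-region human-brain RNA-seq survey: selection of
stably expressed normalizer genes, a filter-cascade caller for allelic
expression imbalance (AEI), ranking of genes by cross-region isoform-usage
deviation, RNA-class detectability/selectivity classification, and
exonic/intronic/intergenic read-partition accounting. Every stage runs
end-to-end on a synthetic-data generator that emulates the structure of a
ten-region x ten-subject brain expression study, so the whole pipeline is
verifiable without any external data.

## Genome partition

Exons of all transcripts are merged (across transcripts and across
overlapping genes) into one exonic set; gene spans minus the exonic set
give introns; the genome minus all gene spans gives the intergenic set.
The three sets are disjoint by construction and cover the genome, which
the test suite verifies base-by-base against a brute-force oracle on
random annotations. Coordinates are 0-based half-open throughout the
package (BED convention); GTF/VCF 1-based inclusive coordinates are
converted only at the I/O boundary.

Read accounting assigns each read to exactly one set. The default rule
uses the read's midpoint base; an alternative (`assignment="priority"`)
takes any overlap with priority exonic > intronic > intergenic. Strand is
ignored for partitioning. Reads on other sequence names (e.g. a
mitochondrial contig) are tallied in a side channel and excluded from the
three-way fractions, mirroring the separate reporting of mitochondrial
and ribosomal reads in this kind of survey. Per-set RPKM is reads in the
set / (set length in kb x total mapped reads in millions); an empty set
has RPKM 0 by convention. Whether input rows represent single ends or
pairs is the caller's business — the summary counts whatever unit the
rows carry.

## Stable-gene selection

**Entropy flatness.** An expression vector (per-region means across the
whole brain, or one region's per-subject values) is normalized into a
discrete distribution and scored by Shannon entropy, which attains its
maximum exactly on the uniform vector. Genes must exceed 3 FPKM
(strictly) in every region to qualify; the normalized entropy
H / log2(n) is thresholded at 0.99 by default. No canonical threshold
exists for "flat", so the threshold is exposed in configuration and the
full ranking is always emitted — any cutoff choice stays transparent.

**I-index reproducibility.** For each gene, m random subsets of k
subjects (k = 2..9; m = min(50, max(10, C(n, k))) subsets per k, sampled
without replacement) yield a regions x k contingency table of the gene's
FPKM. The table is scored with an overlap index built from mutual
information:

    I = 1 - MI(row; col) / min(H(row), H(col)),

which lies in [0, 1] and equals 1 exactly when the columns are linearly
dependent (all subjects share one regional profile up to scale). The
per-gene score is the minimum I-index over all subsets and all k — a
worst-case reproducibility measure. **This functional form is a
reconstruction**: the index is published only by its properties
(positive, bounded by 1, maximal under linear dependence of columns),
all of which this form satisfies and the tests assert.

Two numerical choices matter. First, each column is normalized to unit
sum before forming the joint distribution, making the index exactly
invariant to rescaling any column by a positive constant — a subject's
sequencing depth must not affect pattern overlap (the raw-weight variant
is available via `column_normalize=False`). Second, MI below 1e-10 bits
is clamped to zero, so exactly proportional columns return I = 1.0 to
the bit rather than 1 - 1e-16. FPKM values are used as weights directly,
without integer rounding, to preserve low-expression structure.

## Allelic expression imbalance

Inputs are per-(SNP, subject, region) reference/alternate read counts at
positions genotyped on DNA, plus the subject x SNP heterozygosity mask.
The cascade:

1. keep rows heterozygous for that subject (imbalance is only defined
   between two present alleles);
2. keep rows with combined coverage ref + alt >= 10 reads;
3. keep (subject, SNP) pairs passing the coverage filter in >= 3 regions
   of the same subject — "called in 3 or more regions" is read as
   passing the coverage filter in >= 3 regions;
4. assign SNPs to gene bins (gene spans padded 1 kb each side; a SNP in
   several overlapping bins is scored in each, so overlapping genes with
   identical SNP sets get identical calls);
5. per (gene, subject, region), require >= 2 retained SNPs with pairwise
   distance > 50 bases (longer than a read, so measurements are
   independent). If some pair violates spacing, a maximal spaced subset
   is chosen greedily by descending depth, ties to the lower coordinate.

Each filter stage reports its drop count; rows_in = rows_out + sum of
drops is asserted as an invariant.

Per SNP the allelic ratio is folded, r = max(ref, alt)/min(ref, alt):
phase is unknown, so only the magnitude of imbalance is meaningful, and
folding is the only direction-free summary (unfolded ratios are
recoverable from the input). When the minor allele has zero reads, the
Haldane–Anscombe 0.5 pseudocount is added to both alleles (flagged per
call). The gene-level call reports the arithmetic mean of folded ratios
(a geometric-mean switch exists), mean depth per SNP, and the lower
bound of a 95% confidence interval computed as a t-interval on log2(r)
with n_snps - 1 degrees of freedom, back-transformed. The log-scale
t-interval is symmetric where the folded ratio is not, is defined for
n = 2, and collapses to the point value at zero variance; its center is
the geometric mean, so ci_lower <= mean_ratio always holds.

Tiers: `aei_2fold` when the CI lower bound exceeds 2; the stringent
`aei_2fold_30reads` additionally requires mean depth >= 30 reads per
SNP. The recurrence summary lists genes called at the stringent tier in
two or more subjects of the same region — the signature of a frequent
regulatory variant — with mean +/- SD of their gene-level ratios and
average SNPs per sample.

Calibration and power under the generative model (binomial allele
sampling on negative-binomial depth) are part of the acceptance suite:
with balanced alleles at depth ~50 the twofold-CI tier fires for well
under 1% of genes (the t-interval on 2–4 SNPs is wide, so the criterion
is conservative); with allelic skew 0.75 at depth ~100, planted genes
are recalled at >99% across a 10x10 sample grid and fold near
0.75/0.25 = 3.

## Isoform-usage deviation

The isoform fraction is one transcript's FPKM divided by the summed FPKM
of its gene's isoforms in that sample; zero-total samples are flagged
undefined and excluded from means rather than treated as zero usage.
Genes enter the ranking when they have >= 5 FPKM in >= 40 of the
libraries (both bounds inclusive) and >= 2 isoforms.

For each isoform a 99% confidence band for the grand mean fraction is
formed over all N samples, mean +/- z_0.995 * SD / sqrt(N); a region
whose mean fraction falls strictly outside the band deviates (a value
exactly on the edge is inside). The gene score is the mean over isoforms
of the deviating-region count, so it is bounded by the number of regions
(10). The band must be a confidence interval *of the mean*: a
mean +/- z*SD band over per-sample fractions can never flag a switching
gene, because the switch itself inflates the all-sample SD until every
region mean sits inside — under that reading the maximal observed scores
near 9–10 would be unreachable. The SD band and an empirical-quantile
band are retained as `ci_mode="sd"` / `"quantile"` diagnostics.
Averaging (rather than taking the max) over isoforms matches the
fractional scores this ranking is expected to produce; with the SE band,
pure-noise genes still acquire mid-range scores (a region mean of n/10
samples falls outside a z*SD/sqrt(N) band with appreciable probability),
so the score separates switching genes by ranking, not by a fixed
threshold.

## Detectability and selectivity

A gene is detected in a region when its FPKM exceeds 2 (strictly) in at
least 2 subjects of that region; regions_detected counts regions. The
class summary gives, per RNA class, the distribution of regions_detected
among genes detectable anywhere (the denominator choice is recorded
here: detectable genes, not all annotated genes). The expression-cutoff
ladder counts genes per class whose average FPKM exceeds each cutoff in
a 2–5000 FPKM ladder; the average is the grand mean over all samples
(a per-region option exists). Two inclusion filters used upstream of
differential-expression fitting are provided as standalone operations:
"region" mode keeps genes with > 10 reads in > 8 samples (both strict);
"smoking" mode keeps genes with CPM >= 2 in every sample, CPM = reads
per gene / million aligned reads of that sample. The DE model itself is
deliberately out of scope.

## Synthetic data

The generator emulates the structure, not the biology, of the study
design: 10 subjects (5 smokers / 5 non-smokers, labels carried but with
no planted effect) x 10 named brain regions; three RNA classes —
protein_coding, lncRNA, pseudogene — with per-class lognormal baseline
FPKM (mu = 3.0/1.2/0.8 nats, sigma = 1.0) and per-class probability that
a gene is expressed in a region (0.97/0.55/0.40), encoding broad mRNA
expression versus restricted non-coding expression. Genes are laid on a
single linear toy chromosome with 2–5 exons of 120–300 bp, introns of
100–500 bp, and intergenic gaps; every gene carries 2–4 exonic SNPs with
pairwise distance > 50 bases.

Planted signals: **stable** genes draw a base of 20–80 FPKM with 2%
multiplicative CV across all samples; **region-selective** genes exceed
the detection cutoff only in a designated region subset (8–60 FPKM
there, < 1 FPKM elsewhere); **AEI** genes draw reference counts
Binomial(depth, 0.75) for heterozygous subjects, direction randomized
per gene so the caller cannot exploit a fixed orientation, with depth
negative-binomial (mean 100, dispersion 0.3 — variance m + m^2 d,
matching the overdispersion of real SNP coverage); **switch** genes have
two isoforms whose major role (per-sample major fraction uniform in
0.65–0.85) swaps between a 7/3 region split. Subjects are heterozygous
at all of a gene's SNPs with probability 0.5 (at least one per gene),
and homozygous subjects yield near-pure reference counts (error rate
1e-3) so the heterozygosity filter is exercised. A single integer seed
fixes the entire output byte-for-byte.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: batch and library-preparation effects,
reference-alignment bias at SNPs, correlated noise across genes, RNA
degradation gradients, cellular heterogeneity of dissected regions, and
read-level artifacts (no FASTQ/SAM is produced). The planted effect
sizes are stand-ins chosen for testability, not claims about brain
biology.

## Problem sizes in the test and acceptance runs

The default test fixture uses 50 genes x 100 samples. The acceptance
suite runs the caller at study scale — 2,000 null genes for calibration
(2 subjects x 10 regions, depth 50) and 200 planted AEI genes among
2,000 nulls on the full 10x10 grid (~660k allele-count rows), plus 50
switch genes among 1,000 for the isoform ranking — sizes at which the
measured calibration and recall are stable across seeds while the whole
suite completes in well under a minute.

## Known limitations

* The I-index functional form and the isoform CI band are documented
  reconstructions from stated properties, not published formulas.
* The AEI confidence interval treats per-SNP folded log-ratios as
  exchangeable; linkage between nearby SNPs beyond the 50-base spacing
  rule is not modeled.
* The recurrence summary counts subjects at the stringent tier only; a
  gene imbalanced in many subjects just below threshold is invisible to
  it.
* `stable_within_region` entropy on per-subject vectors conflates
  between-subject biology with noise; it is a screening device, not an
  estimator of variance components.
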