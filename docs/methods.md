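# Methods

## Trans-SNP calling

A *trans-SNP* is operationalised as a site that is (a) an autosomal
biallelic SNV, (b) heterozygous in at least one archaic individual, (c)
contained in the coding-exon union of at least one gene, and (d)
segregating in the modern population sample (0 < alt count < total
called). Condition (b) treats individual-level heterozygosity as evidence
of population-level polymorphism, which is the only reading available when
the archaic sample is a handful of exomes; no per-individual quorum is
imposed. Condition (c) implements the exclusion of UTR and intergenic
variants. Identity of the ref/alt allele pair between the archaic and
modern records is required; positional overlap alone does not qualify.

Missing archaic genotypes ("./.") stay missing and are never imputed.
Chromosome names are normalised by stripping a leading `chr`; VCF
positions are 1-based, all interval arithmetic is 0-based half-open, and
conversion happens only at I/O boundaries.

**CpG handling.** Deamination of methylated cytosine makes CpG
dinucleotides an order of magnitude more mutable, so a shared allele at a
CpG site is far more likely to be identical by state (recurrent mutation)
than by descent. A site is CpG-context when the reference focal base is C
followed by G, or G preceded by C; no methylation map is consulted, so
this is a sequence-context approximation. Analyses run with and without
CpG-context sites; the exclusion is a monotone filter (it can only remove
calls).

## Matched-control enrichment test

Per-gene polymorphism counts are driven by mutational target size (coding
exonic length, overlaps merged before summing), local mutation rate
(GC%, computed over the concatenated coding sequence with non-ACGT bases
excluded from numerator and denominator), and background selection
(McVicker's *B*, the expected surviving fraction of neutral diversity,
consumed as a per-gene table). A control gene is eligible for a target
gene only if all three covariates lie within windows simultaneously —
|ΔB| ≤ 0.1, |Δlength| ≤ 400 bp, |ΔGC| ≤ 5 percentage points, all
inclusive, GC read as absolute percentage points. Control genes are drawn
from the analysis universe minus the full target set; targets with no
eligible control are excluded from both sides of all downstream
statistics, and genes missing any covariate are dropped with a logged
count (no imputation).

Each null replicate draws one control per target uniformly from its
candidate list. Within a replicate an already-drawn gene is skipped while
the target has unused candidates and reused only on pool exhaustion
(counted and reported): a gene set is a set, and allowing duplicates
would deflate the null variance. The test statistic is the set count
(equivalently the per-gene mean, since every replicate has the target
set's size); the test is one-sided for excess, and the empirical p-value
uses the add-one rule p = (r+1)/(n_perm+1), which differs from the raw
proportion by at most 1/(n_perm+1) and never returns 0. Percentile
reports use type-7 (linear-interpolation) quantiles at 5% steps, with the
100th row equal to the maximum; the quantile rule is recorded in the
output metadata so reports are bit-stable.

Because every gene in a genome shares one demographic history, comparing
a target set against same-genome control sets controls demography
implicitly; the covariate matching additionally controls the known
mutational and selective determinants of per-gene diversity.

## Balancing-selection flagging

Negative *F*<sub>ST</sub> estimates are an estimator artifact and are
interpreted as 0 before thresholding; absent values stay absent. A SNP is
flagged when clamped *F*<sub>ST</sub> ≤ 0.04 (threshold inclusive, a
conventional "low differentiation" cut-off) **and** average
heterozygosity > 0.400 (strict), i.e. intermediate allele frequency with
homogeneous distribution across populations. The two reasons are recorded
independently. When two pairwise *F*<sub>ST</sub> values are supplied the
maximum is used — conservative for claiming low differentiation. Tajima's
*D* is reported as context but never thresholded. SNPs lacking either
statistic are unflaggable and listed separately: absence of evidence
never flags.

## Neutral retention

Each lineage is an exact Wright–Fisher population: the derived-allele
count among 2*N*<sub>e</sub> copies is resampled as
Binomial(2*N*<sub>e</sub>, count/2*N*<sub>e</sub>) per generation,
integers throughout, so the simulator is correct at the small
*N*<sub>e</sub> where the dense transition-matrix oracle is feasible.
Replicates in which any lineage has fixed or lost the allele are pruned
from the working arrays, so runtime scales with the surviving fraction.
The diffusion closed form keeps the leading eigenterm,
[6p₀(1−p₀)e^(−t/2Nₑ)]^L capped at 1, and warns when t < 2*N*<sub>e</sub>
where the truncation is inaccurate. Its inversion gives the generations
to a target retention probability, optionally refined by bisection on the
simulator. The default initial frequency is p₀ = ½ — the natural
condition for a polymorphism observed heterozygous at the split; with
*N*<sub>e</sub> = 10,000 the closed form then yields ~1.12% after 53,000
generations, and the exact simulator gives slightly higher values
(~1.15–1.2%), as expected since the single-eigenterm truncation
underestimates the surviving mass. A generation time of 30 years is used
only for annotating reports in years, never in computation.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
per-gene variant counts depending on exonic length and GC (through
CpG-context density), an archaic heterozygosity probability per
polymorphic site, and a sharing probability min(1, f·s) that an
archaic-het site also segregates in the modern sample, where s is the
baseline and f the enrichment factor of the gene's designated set. Modern
allele frequencies conditional on segregating follow a truncated
Beta(0.5, 0.5) — the U-shaped folded spectrum of a large sample — and the
annotation table derives average heterozygosity 2p̂(1−p̂) from the realised
sample frequency, *F*<sub>ST</sub> from two simulated subpopulation
samples via Hudson's estimator (negative draws occur and exercise the
clamp), and Tajima's *D* as configured noise. A truth table records every
site's latent labels, so calls can be audited exactly.

Defaults are 2,000 genes of ~1 kb coding sequence (one plus a
Poisson-distributed number of extra exons, truncated-normal exon
lengths), per-bp polymorphism rate 0.01 and CpG multiplier 2, giving
~20,000 polymorphic sites and a full pipeline run well under two minutes
on one CPU. What the generator does **not** model: linkage and
recombination, coalescent gene genealogies, introgression tracts, and the
empirical archaic/modern site-frequency spectra. Passing tests therefore
demonstrate correctness of the pipeline's logic and calibration of its
statistics under idealised independence, not robustness to the
correlation structure of real exome data.

## Calibration experiments and problem sizes

The type-I experiment runs 200 independent null datasets (f = 1) of 400
single-exon genes with a 40-gene target set and 499 permutations each,
asserting the 5%-level rejection rate inside 0.05 ± 0.03 and p-value
uniformity by Kolmogorov–Smirnov at α = 0.01. The power experiment plants
f = 2 in a 100-gene target set across 50 datasets of 350 genes and
requires median p < 0.05. Single-exon genes with a continuous length
spread (450 ± 90 bp) are used in these experiments deliberately: total
exonic length is then unimodal and the ±400 bp window spans several
standard deviations, the same non-binding role it plays at realistic
scale where exonic lengths are continuous. With few, fixed-length exons
per gene the length distribution becomes multimodal with a mode gap equal
to the window, and window matching then systematically pairs long targets
with the globally more common short controls — a matching artifact real
length distributions do not produce.

Two small-sample properties of the test are worth noting. First, the
count statistic is discrete, and the ≥-tie convention plus the add-one
rule shift the mid-range of the p distribution slightly upward (the tie
mass halves into p), which fades as set counts grow. Second, excluding
target genes from the control universe imposes a finite-population
correction on the null variance (≈ 10% when the target set is 10% of the
universe), a mild anti-conservatism shared by any leave-target-out
permutation design; at the calibration scale used here both effects stay
within the asserted bands.

## Numerical and degenerate-input conventions

Quantiles: numpy type-7 everywhere. Matching thresholds inclusive.
Empty CDS (start == end) yields a zero-exon gene flagged non-coding.
Sites at contig ends treat the absent CpG neighbour as non-matching.
A site in overlapping genes counts once per gene in per-gene tallies and
once in genome-wide totals. Reference-allele mismatches against a
supplied FASTA are reported, never silently fixed. Every reader counts
each dropped record under exactly one reason, so loaded + dropped
partitions the input; the pipeline manifest exposes these counts, the
seed and all thresholds, and is byte-identical across reruns of the same
configuration (wall-clock provenance lives in a separate file).
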