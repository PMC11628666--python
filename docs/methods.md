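# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
design decisions taken where more than one reasonable convention exists.

## Staging

The maturation index `MI = (ES − SP) / (ES + SP)` is computed on section
counts pooled (summed) per bird; summing weights sections by how much tissue
they contain and is stable when individual sections are sparse (averaging
per-section indices would let a nearly empty section dominate). `MI` is
undefined at `ES + SP = 0`; such birds are staged through the qualitative
rules alone.

Stages: *inactive* (no signs of spermatogenesis), *accelerating I*
(spermatocyte division but no elongating spermatids), *accelerating II*
(elongating spermatids, `MI ∈ [−0.7, 0.1]`), *active* (elongating
spermatids, `MI ∈ (0.1, 0.7]`). The boundary `MI = 0.1` is assigned to
accelerating II: the printed ranges overlap at a single point, so a
deterministic convention is required, and the lower window is taken
closed-on-the-right. Birds with elongating spermatids but `MI` outside
`[−0.7, 0.7]` are flagged unstageable (returned, not raised). The
spermatocyte-division flag is external input (scored on the sections); it is
never inferred from the counts. Stages pool into EARLY = {inactive,
accelerating I} and LATE = {accelerating II, active}.

## Expression

**Prefilter.** On a working copy, counts below `min_per_sample` (default 10)
are floored to zero; a gene is retained iff at least `min(group sizes)`
samples keep a working count ≥ 10 *and* the working counts total ≥ 320.
Downstream analysis uses the original counts of the retained genes — the
flooring exists only to make the support rule robust to scattered low
counts. The rule is idempotent.

**TMM.** Normalization factors are the trimmed (30% of log-ratios, 5% of
average abundances, by ranks with average ties), inverse-variance-weighted
mean of per-gene log2 ratios against a reference sample (the one whose
upper-quartile/library-size ratio is closest to the cohort mean), rescaled
to geometric mean 1. The implementation reproduces the reference R
implementation to machine precision (`tests/test_r_oracle.py`).

**log-CPM.** `log2((y + 0.5) / (N·f + 1) × 10⁶)` with effective library
sizes `N·f`.

**Precision weights.** Per-gene residual standard deviations from an
unweighted fit of the cell-means design; `sqrt(sd)` is smoothed against mean
log-count with lowess (span 0.5, 3 robustifying iterations) and the trend is
evaluated at each observation's fitted log-count; the weight is the fourth
inverse power of the trend value (floored at 1e-6 against degenerate
trends). When effective sizes are not supplied the abscissa is mean log-CPM,
which differs only by a per-sample shift.

**Moderated contrasts.** Per gene, weighted least squares on the six
karyotype × development-group cell means; per contrast `c`, effect `c'β`
with unscaled variance `c'(X'WX)⁻¹c`. Residual variances are shrunk toward a
prior fitted by closed-form method of moments on the log variances (the
scaled-F model: the excess variance of `log s²` over `trigamma(d/2)`
identifies the prior df via the inverse trigamma; the mean identifies the
prior variance). No robustified or trend-based prior is offered — the
smallest faithful implementation with testable limit behaviour: prior df 0
reproduces ordinary weighted t-statistics exactly, prior df ∞ pins every
variance to the prior. Total df is capped at the pooled residual df, and
with infinite prior df the prior variance is the mean residual variance —
two details adopted from the published implementation, against which the
statistics agree to ~1e-14.

Contrasts: testis tests the three pairwise karyotype differences within
EARLY and within LATE (six contrasts); liver first averages each karyotype
over the two development groups with *equal weights* (the cohort is nearly
balanced; sample-size weighting would tie the contrast definition to the
realized design) and then takes the three pairwise differences.

**Global decision.** Benjamini–Hochberg is applied once to the pooled
vector of all gene × contrast p-values with a single cutoff (α = 0.05
default); decisions are up/down by effect sign. A gene is "DE" if
significant in ≥ 1 contrast. Because the multiplicity control operates at
the gene × contrast level, false-discovery calibration is also assessed at
that level: the proportion of decisions contradicting the planted truth is
≤ 0.10 in the recovery suite, whereas a gene-level proportion would be
inflated mechanically (each true gene contributes several significant
contrasts while false rejections scale with the total rejection count).

**Clustering.** DE-gene profiles are standardized to Z-scores across samples
(zero-variance rows map to zero), then hierarchically clustered with
Euclidean distance and Ward linkage, cutting the tree at k = 10 clusters by
default. The cluster count is a display-level choice; distance/linkage were
fixed to the common default for expression heatmaps and the procedure is
deterministic.

## Genomic enrichment

Windows tile each chromosome with step = window_size / steps_per_window
(4 Mb windows, 4 steps for testis; 8 Mb for the gene-sparser liver), so each
interior basepair lies in exactly four windows. A gene belongs to a window
iff its start coordinate falls inside it (unambiguous for genes spanning
window edges). Per window, the upper-tail hypergeometric probability of its
DE count given its expressed count and the chromosome-wide totals is
computed; BH is applied across all windows and windows with adjusted
q < 0.01 are merged into enriched regions when they overlap. On null
simulations the discrete, conservative hypergeometric tail keeps the false
window rate essentially at zero.

The chromosome-bias test is a 1-df Yates-corrected goodness-of-fit of the
observed (Z, autosome) DE counts against expectations proportional to the
annotation ("genome" background); a 2×2 contingency mode with Yates
correction is available as a flag, as is an expressed-genes background
(pass the retained genes as the universe). Scaffolds — chromosome labels
that are neither `Z` nor numeric — are excluded from both partitions.
Expected cells below 1 set a warning flag but the statistic is still
returned.

The Z:autosome ratio is the median log-CPM of Z genes over the median
log-CPM of autosomal genes per (karyotype, tissue, timepoint) group, over
retained genes only; a zero autosomal median flags the ratio undefined
rather than raising.

## Allele-specific expression

Variant filtering applies the stringent transcriptome thresholds: sites
with QUAL < 999, indels, or INFO/DP < 640 are removed; genotypes with
DP < 8 or GQ < 10 are set missing and their allelic depths zeroed; the
merged-tissue mode additionally drops sites with any missing genotype.
Multi-allelic records are decomposed into biallelic rows on read.

Tag-SNP assignment formalizes what is otherwise a manual curation step:
allelic depths are pooled across AA samples and across BB samples
(heterokaryotypes never contribute); the candidate A allele is the AA-major
allele, and the SNP is *informative* iff that allele's pooled fraction is
≥ 0.9 in AA and ≤ 0.1 in BB with both pools ≥ 20 reads. Both thresholds are
configurable; near-fixed rather than fully fixed SNPs are admitted because
transcriptome cohorts rarely yield complete fixation. SNPs that fail the
rule are dropped as non-informative — with 2% haplotype leakage roughly 2%
of genuinely diagnostic SNPs are not near-fixed in a 32-bird sample, and
declining to assign them is the correct behaviour, so assignment quality is
reported as precision over the assigned SNPs together with recall over the
planted truth.

The per-gene ASE profile is `p_A = Σ depth(A) / Σ depth(A) + depth(B)` over
all informative SNPs in the gene, per sample; zero informative depth flags
the row undefined. `p_A` is invariant to splitting a SNP's depths across
records and label-swapping maps `p_A → 1 − p_A` (both property-tested).

Dominance patterns are classified from the fitted cell means: per
development group the score `δ = (μ_AB − μ_BB) / (μ_AA − μ_BB)` is 1 when
the heterokaryotype matches AA and 0 when it matches BB; the expression is
invariant to negating all means, so the labels are orientation-free. With
tolerance τ = 0.25, a group is A-like (δ ≥ 0.75), B-like (δ ≤ 0.25) or
intermediate, and the EARLY/LATE pair maps to: (A,A) → A-dominant,
(B,B) → B-dominant, (I,I) → intermediate, any pair mixing intermediate with
a homokaryotype-like state → divergent over time (the taxonomy distinguishes
no direction for that transition), (A,B)/(B,A) → switching. Genes with
|μ_AA − μ_BB| < 1 log2 unit in either group are unclassified — below that
separation δ is numerically unstable and the pattern scientifically
meaningless.

## Inversion landscape

Genotype dosages are polarized toward AA: at each SNP the allele with
majority dosage among AA samples becomes the zero state (ties keep the
reference allele), making inversion blocks visible as a 0/1/2 banding of
AA/AB/BB samples. Polarization is idempotent; SNPs without a genotyped AA
sample are dropped with a log record.

Block segmentation: per SNP, `d = |AF_AA − AF_BB|` from pooled allele
frequencies; a centred moving average over m = 11 SNPs is thresholded at
0.8 to find candidate runs. The centred average alone erodes each block edge
by roughly half the smoothing window (≈ 2 Mb at 0.5 Mb SNP spacing), which
would bias breakpoint estimates inward, so run edges are refined outward
over contiguous raw `d ≥ 0.8` SNPs; detection still happens exclusively on
the smoothed profile, so the null behaviour (no blocks on undifferentiated
chromosomes) is unchanged. Block bounds extend half-way to the neighbouring
SNP. Pairwise r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples; zero-variance pairs are flagged degenerate.

Family structure is not modelled in the analysis; allele-specific expression
can in principle distort transcriptome-derived genotypes of heterokaryotypes
(a monoallelic gene yields an apparently homozygous call), and no correction
is applied — profiles from such genes should be read with that caveat.

## Synthetic data

The generator's defaults are the study conditions: the 32-bird design
(3/3/3/3 AA, 2/3/2/3 AB, 2/2/3/3 BB across the four timepoints), both
tissues per bird, three inversion regions on Z at 22.5–27.9, 33.5–39.9 and
64.0–68.9 Mb, negative-binomial counts with dispersion 0.1 (BCV ≈ 0.32,
typical for outbred laboratory cohorts) and gene baselines log-uniform on
20–500 expected counts, cis and trans karyotype effects of 2 log2 units,
per-haplotype fixation 0.98 at diagnostic SNPs, ~2 SNPs/Mb along Z (all
placed inside genes, as transcriptome variants are), and Poisson(50) allelic
depth per SNP and sample — sequencing depth per SNP is not a reported
quantity, so 50 is a plausibility choice for deep bulk RNA-seq, not a datum.

Heterokaryotype allelic depths at diagnostic SNPs are Binomial(depth, p_A)
with gene- and tissue-specific `p_A` (default 0.5; the planted
tissue-specific case is monoallelic in testis and balanced in liver), and
heterokaryotype genotypes at diagnostic SNPs are het. The fixation leakage
is applied to homokaryotype haplotypes only: a read-level error model would
bias recovered heterokaryotype proportions by ≈ (1 − 2p)(1 − fixation),
confounding the parameter-recovery checks, while the committed model keeps
the AB estimator unbiased and still produces pooled homokaryotype
major-allele fractions ≈ 0.98. Histology counts are rejection-sampled until
the pooled index lands inside the planted stage's window, so staging is
always recoverable. A single seed drives one SeedSequence; all component
streams are spawned from it, and equal configurations with equal seeds give
byte-identical output files.

What the generator does **not** emulate: read-level artifacts (mappability
and reference bias in allelic depths), family-correlated haplotype sharing,
GC/length effects on counts, tissue-specific baseline expression
differences, and overdispersion of allelic counts beyond binomial. Passing
recovery tests therefore demonstrates the correctness and calibration of the
procedures under the stated generative model, not robustness to those
real-data complications.

## Problem sizes and determinism

The test suite runs the statistical checks at the scale the procedures are
specified for: calibration and recovery on 2,000-gene, 32-sample cohorts
(3 seeds), allele-proportion recovery on 10 replicates of a 7-bird
heterokaryotype-focused design, breakpoint recovery on 10 planted and 50
null chromosomes at 0.5 Mb SNP spacing, and window enrichment on 50 null
and 20 planted chromosomes of 800 genes. All random draws in tests and
simulations are seeded; hypothesis profiles are derandomized.
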