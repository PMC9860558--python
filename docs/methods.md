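# Methods

This note records the statistical models, the synthetic-panel design, and the
numerical choices behind `sesapop`, in the spirit of a model-documentation
page: what is computed, under which assumptions, and where the design was
genuinely open.

## Estimators

**Nucleotide diversity.** Per site, with m non-missing haplotypes (2 × called
diploids) and ALT frequency p̂, diversity is the unbiased expected
heterozygosity 2p̂(1−p̂)·m/(m−1), which equals the mean pairwise difference
among the m haplotypes; the identity is exercised by an exhaustive
enumeration oracle in the tests. Window π sums site values over a 10 kb
non-overlapping window and divides by the window length in bp, so
monomorphic positions enter through the denominator. Windows tile each
chromosome; the terminal window is truncated.

**Watterson's θ and Tajima's D.** D uses the complete-case convention: only
samples non-missing at every SNP in the window contribute, so the haplotype
count n is constant within the window (the convention of the common
command-line implementations). D = (π̂ − θ_W)/√(e₁S + e₂S(S−1)) with the
standard constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ of the 1989 derivation;
π̂ here is the un-normalized sum of mean pairwise differences. S = 0 returns
missing and is excluded from group means. The worked four-haplotype example
(S = 3, D = +0.168) is frozen in the tests, and windows drawn from the
neutral frequency spectrum (allele counts ∝ 1/k) average D ≈ 0, because
under that spectrum E[π per site] = 1/a₁ exactly.

**F_ST.** The Weir & Cockerham (1984) estimator from genotype data: per-site
variance components a (among populations), b (among individuals within
populations), c (within individuals), computed from per-population sample
sizes, ALT frequencies, and observed heterozygote proportions. Sites where
any population has fewer than two called diploids, or where a+b+c = 0, are
excluded. Windows and genome-wide values combine sites by ratio of sums
Σa/Σ(a+b+c) (the "weighted" estimator); a mean-of-ratios mode exists because
genome-wide published values are sometimes simple window averages, but ratio
of sums is the default and the one validated by parameter recovery. Negative
window estimates are retained so genome-wide sums stay unbiased; clamping is
cosmetic and left to plotting.

**LD decay.** Inputs are unphased, so r² is the squared Pearson correlation
of ALT-dosage vectors over the pair's shared non-missing samples (genotype
r², the resequencing-panel default). All intra-chromosomal pairs within
500 kb are binned at 1 kb; above a 10⁷-pair budget, pairs are subsampled
uniformly with a fixed seed. The curve is smoothed by a centered rolling
median over 5 bins before feature extraction, and the half-decay distance is
the first distance at which the smoothed curve falls to half its observed
maximum, linearly interpolated between straddling bins. "Maximum" means the
observed smoothed maximum, not a fitted intercept — with dense data the two
agree, and the observed maximum needs no model.

**Sweep calling.** For a focal group against a background group, each window
gets (F_ST, log₂(π_b/π_f)); the orientation puts a focal-group sweep at
positive scores. Windows with π_b = 0 are uninformative and excluded; π_f = 0
with π_b > 0 is assigned a cap of 10 (≈ a 1000-fold reduction) so region
peak statistics stay finite. Fixed mode flags windows with F_ST > 0.45 AND
log₂ ratio > 2.5 — both criteria are required; quantile mode flags the
intersection of the top 5% of both statistics. Flagged windows within one
window of each other merge into regions (configurable), and genes overlap a
region with ≥ 1 bp. High/low trait groups use strict inequalities
(> 6 mg/g, < 1 mg/g for a sesamin-like trait) and downstream scans warn
below 10 accessions per group.

**BLUP.** Across environments the phenotype model is
y_ij = μ + env_j (fixed) + g_i (random, σ_a²) + ε_ij, fitted by REML
(statsmodels `MixedLM` under the hood); the per-accession value is the
fixed-effect prediction at the average environment plus the accession BLUP.
In the balanced case the BLUP shrinks the env-adjusted accession-mean
deviation by σ_a²/(σ_a² + σ_e²/r) with r environments — the tests verify
this closed form against the fitted components. When the env-adjusted
within-accession residual variance is numerically zero the model returns
env-adjusted means directly: REML is unstable at the σ_e² → 0 boundary and
the means are the exact limit. A single environment yields centered means
with a warning (no shrinkage is identified).

**Mixed-model association (EMMAX approximation).** y = Xβ + u + ε with
u ~ N(0, σ_g²K) and K the standardized (VanRaden) relationship matrix
ZZᵀ/m, z = (x − 2p)/√(2p(1−p)), missing dosages mean-imputed. K is
eigendecomposed once; the restricted likelihood is profiled over
δ = σ_e²/σ_g² on a 100-point log₁₀ grid in [−5, 5] with bounded scalar
refinement (tolerance 10⁻⁶); hitting the grid boundary raises a warning
(pure-noise traits legitimately drive δ to the upper bound). Each SNP is
then tested by GLS under the fixed V̂ with a Wald t-test at n − rank(X) − 1
degrees of freedom, with the residual scale re-estimated per SNP. An exact
mode re-optimizes δ per SNP (full per-SNP REML); the EMMAX p-values track it
at Spearman ρ > 0.99, which the tests assert on a 200-SNP panel. With K = I
the scan reduces to ordinary per-SNP regression to 10⁻⁸, a degenerate case
the tests also pin. No principal components enter as covariates by default
(K absorbs smooth structure); a `--pcs` option exists. Significant sites use
strict −log₁₀p > 6 and collapse to the peak site per ±89 kb LD window — the
same radius used for candidate-gene windows, keeping locus counting and
gene extraction consistent. λ_GC is the median χ²₁ quantile over 0.4549.

**Allele effects.** The panel is inbred (selfed for generations), so
heterozygotes are excluded by default (a "separate" policy exists) and the
two homozygote groups are compared with Welch's unequal-variance t-test
(Welch–Satterthwaite df). Welch rather than pooled-variance Student is the
robust default for unequal group sizes; group sizes at a favorable-allele
locus are typically very unequal. The superior allele is the higher-mean
group's allele (direction configurable), flagged significant at p < 0.05.

## Synthetic panel

The generator produces the study conditions the estimators are validated
under, with closed-form truth wherever possible.

**Structure.** Each site draws an ancestral frequency p ~ Uniform(0.05,
0.95) — bounded away from the MAF-filter boundary so filtering does not
distort recovery experiments — and each subpopulation's frequency from the
Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F); genotypes are binomial(2, p)
per diploid, i.e. Hardy–Weinberg within populations. F is per population;
a two-population panel with both at F recovers F under the Weir–Cockerham
estimator, the identity the acceptance checks use at the published
genome-wide values (0.068, 0.156, 0.159) and group sizes (257/92, 61/257,
61/92). Missing calls are injected at 2% and depths as Poisson(25),
mirroring a ~25× panel, so the depth and missingness filters have work to
do. REF/ALT pairs are drawn with transition weight 3.8, giving Ts/Tv ≈ 1.9.

**Sweeps.** A hard sweep fixes the alleles carried by the single haplotype
the favored mutation arose on. The planting therefore drives each site in
the interval, with probability `intensity`, to fixation at the allele of one
random focal haplotype (ALT with probability p); escaping sites get a
multiplicative push toward their nearer boundary by (1 − intensity).
Intensity 1 leaves the focal group monomorphic; 0 is a strict no-op. The
random-haplotype component is essential, not decorative: fixing only
toward the nearer (major-allele) boundary caps expected window F_ST near
0.35 regardless of intensity, because the background's heterozygosity
remains in the denominator — no deterministic major-allele push can produce
the joint F_ST > 0.45 / log₂ ratio > 2.5 signature. With the
random-haplotype mechanism at intensity 0.9 over background F = 0.05,
planted windows run at F_ST ≈ 0.51 ± 0.03 and log₂ ratio ≈ 6, giving the
caller ≥ 0.9 recall at ≤ 0.1% neutral false flags (measured over 100
replicates in the tests).

**LD.** Haplotypes copy from a founder pool (founder alleles Bernoulli(½)),
switching to a uniformly drawn founder between adjacent sites with
probability 1 − (1 − r)^gap; copies pair into diploids. Mean r² decays from
the founder-class correlation toward the finite-sample baseline ≈ 1/n. The
truth for half-decay recovery is measured on a 10× larger sample of the same
process rather than derived analytically.

**Trait.** g_i = Σ effect_k · dosage_ik over planted causal sites;
y_ij = μ + env_j + g_i + ε with Var(ε) = Var(g)(1−h²)/h², so a single
observation has heritability h². μ defaults to 2.5 mg/g with effects on the
order of 1 mg/g, placing simulated panels inside the observed sesamin range
(0.06–10.65 mg/g); values are not clipped at zero, preserving the linearity
the BLUP tests rely on. h² = 0 zeroes the genetic values (with a warning if
effects were supplied) and uses unit residual variance.

**What the generator does not emulate.** Coalescent genealogy and
recombination-linked site correlation in the structure model (sites are
exchangeable given frequencies), forward-in-time selection dynamics,
gene-flow graphs, InDels, genotyping error beyond missingness, and
environment-by-genotype interaction. Passing tests therefore demonstrate
estimator correctness under the declared frequency models, not robustness
to every artifact of real resequencing data.

## Problem sizes

The validation suite runs at desk scale by design: 20,000 SNPs for F_ST
recovery, 5 Mb / 500 windows for π recovery, 100 replicate genomes of 50
windows for sweep operating characteristics, and 400-sample panels for GWAS
calibration (20 null replicates) and power (50 replicates). These sizes put
Monte-Carlo error well inside the 5–10% tolerances being asserted while the
whole suite completes in about a minute.

## Degenerate inputs and tie-breaks

Sites with under two called diploids contribute nothing to π; windows with
S = 0 have undefined D; pairs with a monomorphic shared set have undefined
r²; all are propagated as missing, never as zero. Collinear or
post-imputation-monomorphic SNPs in the scan get p = 1 with a flag rather
than an exception. Equal allele-group means yield no superior allele. The
filter applies depth masking before MAF/missingness so the three criteria
compose deterministically; "depth ≥ 8×" is read per genotype (masking),
with a per-site-mean mode available since the per-site reading is also
defensible. Multi-allelic records are excluded, not split: every downstream
statistic assumes biallelic sites.
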