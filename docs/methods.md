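# Methods

`proxygwas` implements a proxy-phenotype (GWAS-by-proxy / GWAX) analysis in
which a genotyped offspring's self-report of a *parent's* disease status is
used as the phenotype, so that a disease of old age can be studied in a
middle-aged cohort. The package covers the full analysis chain — phenotype
construction with exclusion rules, residualized linear-model association,
conversion of linear coefficients to case–control-scale odds ratios with the
parent–offspring ×2 rescaling, staged inverse-variance meta-analysis, locus
definition, and gene-based testing — together with a trio-cohort simulator
that carries the ground truth needed to validate every step.

## The generative model

Each simulated family consists of two latent parents and one genotyped
offspring.

**Genotypes.** Every SNP j has an allele frequency p_j drawn uniformly from
`maf_range` (default (0.05, 0.5]). Each parent receives two haplotypes with
Bernoulli(p_j) alleles, so parental genotypes are Hardy–Weinberg at p_j; the
offspring receives one allele from each parent, chosen uniformly from the
parent's two (Mendelian transmission). This makes the offspring–parent dosage
correlation exactly 1/2 per SNP, the quantity that motivates the ×2 effect
rescaling. Optionally, haplotypes can be given block LD via an AR(1) Gaussian
copula (`ld_block_size`, `ld_rho`), with block-wise transmission so the
offspring preserves the LD; this mode feeds the locus-definition and
gene-based nulls, which need correlated SNPs.

**Disease.** Parental disease is logistic in the *parent's own* genotype:
P(D | g) = logistic(α + Σ_j β_j g_j), with β_j = `causal_log_or` at the
`n_causal` causal SNPs (scalar or per-SNP values) and 0 elsewhere. The
intercept α is calibrated per parent by root bracketing (Brent) so that the
population-average risk over the simulated genotypes equals the configured
prevalence to better than 1e-6 — maternal k = 0.096 and paternal k = 0.055 by
default, the observed sample prevalences of the family-history phenotype this
design targets (their 1.7-fold ratio reflects sex differences in longevity).
A logistic rather than liability-threshold model was chosen because it gives
a direct per-allele log-odds truth to compare against recovered odds ratios;
the marginal allelic odds ratio it implies is computed exactly by
`true_allele_risks`/`true_allelic_or`, which integrate the risk over the HWE
distribution of the causal background (enumeration up to 13 background SNPs,
Monte Carlo beyond), or by direct tabulation over a fresh simulated parent
population. Note the marginal allelic OR is slightly attenuated relative to
exp(β_j) (non-collapsibility of the odds ratio); the exact oracle, not
exp(β), is the estimand against which recovery is scored.

**Reporting and exclusions.** The offspring reports each parent's status with
`report_sensitivity` (default 0.85) and `report_specificity` (default 0.99) —
plausible informant-report error rates; no published value exists for this
questionnaire, so they are exposed as parameters. Statuses are set to missing
when the parent is under 60, died before 60, or has no age information, the
exclusion rules of the family-history phenotype; parental ages are Normal
(mean 78, SD 9 years) with configurable death-before-60 (0.04) and
missing-age (0.02) probabilities. Covariates (assessment centre, genotype
batch, array, 10 principal components, parental age) are simulated as pure
noise by default; `covariate_report_effect` can tilt reporting probability
along PC1 to emulate ascertainment artifacts. All randomness flows from one
seeded generator; identical configurations reproduce bit-identical cohorts.

## Association and effect transformation

The phenotype of the GWAS is the least-squares residual of the observed
status on the covariates, fitted per parent on that parent's non-missing
rows (the maternal and paternal analyses have different n). Each SNP is then
tested by simple linear regression of the residuals on offspring dosage;
p-values use the normal approximation to the t statistic, appropriate for
the large samples the design targets. SNPs with analyzed minor allele
frequency ≤ 0.01 are removed (an imputation-quality filter at 0.3 applies
when info scores are supplied; simulated dosages are exact).

A linear coefficient β on a binary trait of prevalence k implies allele-level
risks P(D | A1) = k + β(1−p) and P(D | A2) = k − βp; the allelic odds ratio
is the cross-product of that 2×2 table,

    OR = ((k + β(1−p)) (1 − k + βp)) / ((k − βp) (1 − k − β(1−p))),

with k the *observed prevalence of the analyzed sample*. Because the proxy
regression estimates half the parental effect (offspring–parent dosage
correlation 1/2), the log-odds are multiplied by two; the SE of the scaled
log-odds is recovered from the adjusted OR and the unchanged p-value
(SE = |log OR| / z), which keeps the z statistic identical to the linear
model's. The two-sided p → z map uses the upper-tail quantile at p/2 and
falls back to the linear z below p ≈ 1e-300, where the quantile is
unreliable. Per-SNP domain failures (an implied cell probability ≤ 0 at
extreme frequency × effect combinations) are flagged rows, not fatal errors,
and are excluded from meta-analysis.

**Accuracy of the ×2 rescaling.** Doubling the log of a nonlinear transform
of β/2 is a first-order identity: 2·ln LMOR(β/2) − ln LMOR(β) =
−LMOR″(0)β²/4 + O(β³), an upward bias of about +0.2–0.5% on an OR of 1.2 at
k = 0.055–0.096. The recovery tests therefore check the pipeline against the
method's exact closed-form expectation 2·ln LMOR(β_lin/2) at two-SE
precision, and against the nominal OR with a tolerance that covers this
documented approximation error.

## Meta-analysis

Fixed-effects inverse-variance (SE-weighted) combination: weights 1/SE².
The staged design combines the two proxy GWAS first and then adds the
external case–control consortium's stage-2 effect where a SNP has stage-2
results, otherwise its stage-1 effect; by associativity of fixed-effects
IVW the staging only decides which consortium effect is eligible. Alleles
are harmonized to the first cohort carrying each SNP (sign flip on swapped
alleles, exclusion with a warning when unreconcilable); palindromic A/T and
C/G pairs pass through with a warning since no frequency-based strand
resolution is attempted (all in-scope data are self-generated with
non-palindromic pairs). The four-character direction string records each
cohort's sign in the fixed order (maternal, paternal, stage 1, stage 2),
with '?' for a cohort that did not contribute the SNP — stage 1 therefore
shows '?' whenever stage 2 contributed, mirroring the staged input actually
given to the combination.

**Overlapping controls.** The validity check for analysing the two parents
separately despite shared (offspring) controls compares a single GWAS of the
0/1/2 count of affected parents with the meta-analysis of the separate runs.
The combined run analyzes every offspring with *at least one* observed
parental status (a missing parent contributes no affected count); under this
definition the combined statistic is essentially the IVW meta-analysis
itself, and the per-SNP p-value correlation at the default simulation size
is ≈ 0.99 with a −log10 p regression intercept ≈ 0 and slope ≈ 1.
Restricting to offspring with both statuses observed (`rows="both"`) caps
the correlation near the square root of the row overlap (~0.91 under the
default exclusion rates) and is available for comparison.

## Locus definition

From a reference dosage panel, signed LD r is computed within a 1 Mb window
(r = 0 beyond; monomorphic SNPs flagged NaN). Independent significant SNPs
are selected greedily in ascending-p order (ties: position, then id) among
SNPs with P < 5e-8, requiring r² < 0.6 to all previously selected; lead SNPs
repeat the rule within the independent set at r² < 0.1. Lead SNPs within
250 kb of each other (between lead positions, iterated to closure via
union-find) merge into one locus, whose members are all panel SNPs with
r² ≥ 0.6 to any of its independent significant SNPs — member significance is
not required (a configurable choice). Memberships on a chromosome are
disjoint: a SNP reachable from two loci joins the one with the smaller
top-lead p. On instances of ≤ 10 significant SNPs the greedy output is
verified against exhaustive enumeration.

## Gene-based testing and enrichment

The gene statistic is the SNP-wise mean chi-square, T = (1/m) Σ z_j², with a
constant sample size assumed across SNPs. Its null under LD is the mean of
squares of a zero-mean multivariate normal with the SNPs' signed correlation
matrix (eigenvalues clipped at zero when slightly non-PSD; grossly non-PSD
matrices are rejected). The tail is estimated by Monte Carlo (default 1e6
seeded draws, p = (count+1)/(n+1)) or by a moment-matched scaled chi-square
(T ≈ (V/2)·χ²_{2/V} with V = 2 Σ r_ij²/m²), which is exact for independent
SNPs and a two-moment approximation under LD (deviations up to ~0.05 in
absolute p under strong LD — use the Monte Carlo path when precision
matters). Genes are significant at the Bonferroni threshold 0.05/(number of
genes tested). Gene-set enrichment is the one-sided Fisher exact
(hypergeometric) tail of the 2×2 in-set × significant table, with fold =
observed/expected.

## Diagnostics

Genomic inflation is λ = median(z²)/0.454936 (the 1-df chi-square median).
The overlap-sensitivity report gives the p-value correlation on both the raw
and −log10 scales (the regression uses −log10). Recovery reports score the
scaled log-OR against the exact marginal allelic truth per causal SNP (bias,
RMSE, 95% CI coverage). Misclassification attenuation is reported, not
corrected: with the default sensitivity 0.85/specificity 0.99 the observed-
status effect, and hence the recovered OR, is attenuated — the recovery
validations therefore run with perfect reporting, since the property under
test is the ×2 rescaling of the observed-status odds ratio, not informant
accuracy.

## Validation problem sizes

The test-suite and acceptance-script runs use these sizes, chosen to make
each tolerance statistically meaningful at desk scale:

- Overlap sensitivity: 20,000 offspring × 2,000 SNPs, 50 causal SNPs with
  per-allele log-OR 0.18, prevalences 0.096/0.055 (the default
  configuration), fixed seed.
- Proxy-scaling recovery: 50 replicates × 50,000 trios × 30 SNPs (8 causal,
  parental allelic OR 1.2, perfect reporting); 400 causal estimates.
- Null calibration: 10 independently seeded null cohorts of 800 offspring ×
  10,000 SNPs, pooled to 100,000 z-statistics (the sampling SD of λ is
  ≈ 3.1/√M, so M = 1e5 supports a ±0.02 check); the gene-based null uses
  4,000 offspring × 720 SNPs in 6-SNP LD blocks, 120 genes, 1e5 Monte Carlo
  draws per gene.

## What the simulator does and does not emulate

It reproduces the statistical structure the method relies on: Mendelian
parent–offspring dosage correlation, prevalence-calibrated binary disease,
informant misreporting, age-based exclusions, nuisance covariates and
optional block LD. It does not model population structure beyond PC
covariates, relatedness between offspring (sibling pairs sharing parents),
imputation uncertainty, X-chromosome inheritance, or realistic genome-wide
LD; passing tests therefore demonstrate the method's internal validity, not
robustness to those real-data complications.

## Known limitations

- The per-SNP regression reuses the covariate-residualized phenotype without
  adjusting the residual degrees of freedom, exactly as large-cohort GWAS
  software does; at very small n with many covariates this inflates z²
  slightly (≈ +1% at n = 800 with ~25 covariate columns).
- The ×2 rescaling's O(β²) bias (above) is inherent to the reported method.
- The Satterthwaite gene path is approximate under strong LD.
- Fixed-effects only; no heterogeneity statistics are computed.
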