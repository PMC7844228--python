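# Methods

This note records the statistical model behind each stage, the numerical
choices, the design of the synthetic-data generator, and the limits of what
the passing tests demonstrate.

## Summary-statistic model

All gene-level inference starts from the standard asymptotic result that
the vector of marginal z-scores `z_j = beta_j / se_j` of the SNPs in a
region is multivariate normal with correlation matrix equal to the genotype
correlation (LD) matrix `R`: `z ~ N(mu, R)`, `mu = 0` under the null. `R`
is estimated as the Pearson correlation of dosage columns in a reference
panel (missing dosages mean-imputed per SNP). Sampling noise can make the
estimate indefinite, so before any quadratic-form computation `R` is
projected to the positive-semidefinite cone by clipping negative
eigenvalues at zero and renormalizing the diagonal to one.

Input QC retains SNPs with MAF ≥ 0.001 and INFO ≥ 0.8 (exclusion is the
strict inequality, so exact-boundary records survive). Reported p-values
are validated against `beta/se` under a two-sided normal test at relative
tolerance 1e-3; discrepancies warn rather than fail, because published
files round.

## Gene-level tests

SNP weights default to the Beta(MAF; 1, 25) density (`WeightScheme`),
the rare-variant-upweighting convention of the summary-statistic
kernel-test literature; equal weights are available. The per-method
internals — the rho grid {0, 0.01, 0.04, …, 0.81, 1}, the Beta(1, 25)
weights, the 85% PCA variance fraction — are documented assumptions
exposed in configuration, since only the method names are fixed by the
analysis design.

**Quadratic-form tails.** `quadform_pvalue` computes
`P(sum_r lambda_r chi2_{1,delta_r^2} >= q)` by Imhof's inversion formula,
integrated over oscillation-adaptive panels with an integration-by-parts
closure of the oscillatory tail (absolute target 1e-9, configurable).
Equal-eigenvalue central mixtures short-circuit to the exact chi-square
closed form. Below p ≈ 1e-8, where any absolute-tolerance quadrature loses
relative accuracy, the tail probability is recomputed by numerical
inversion along the saddlepoint contour: on that path the integrand is a
smooth Gaussian-decaying bump, so the result keeps ~1e-10 *relative*
accuracy arbitrarily far into the tail (validated against scaled and
noncentral chi-square closed forms). A Lugannani–Rice saddlepoint and the
Liu et al. four-moment approximation remain as fallbacks; p-values are
floored at 1e-300 to keep log transforms finite.

**SKAT-O.** For each grid value,
`Q_rho = z' W^{1/2}[(1-rho)I + rho 11']W^{1/2} z` with per-rho null
weights `eig(Phi^{1/2} M_rho Phi^{1/2})`, `Phi = W^{1/2} R W^{1/2}`. The
omnibus p-value is computed *exactly* rather than by the usual
variance-adjusted one-dimensional approximation: writing `y = W^{1/2}z`,
`u = 1'y` (burden component, variance `s = 1'Phi 1`) and `x = u²/s ~
chi2_1`, every `Q_rho` is, conditional on `x`, a monotone function of the
single noncentral quadratic form `D` with weights `eig(Phi − cc'/s)`,
`c = Phi 1`. Hence

    P(min_rho p_rho < T) = E_x[ sf_D( d(x) | x ) ] + P(x > x_max),

where the thresholds entering `d(x)` are the per-rho quantiles at the
observed minimum p-value `T` (the argmin rho needs no inversion — its
threshold is the observed statistic). The outer expectation is a 48-node
Gauss–Legendre integral in `t = sqrt(x)`; inner probabilities use the
machinery above at tolerance 1e-6. The exact construction makes null
SKAT-O p-values uniform by the probability integral transform and agrees
with a 10⁶-replicate Monte-Carlo simulation of the min-p statistic within
Monte-Carlo error (tested). If the integration fails the code falls back
to the Bonferroni bound `min(1, T × grid size)`; the result is always
clipped to the bracket `[T, T × grid size]`.

Degenerate cases: a single SNP returns the per-SNP chi-square p for every
rho; a burden-degenerate gene (`s ≈ 0`, possible under negative LD)
returns the Bonferroni bound.

**PCA test.** Components are retained until the cumulative eigenvalue
fraction reaches `var_fraction` (0.85); `T = sum (q_i'z)²/lambda_i` is
referred to chi-square with k df. A zero retained eigenvalue (perfectly
collinear LD after regularization) is an error rather than a silent
answer.

**ACAT-V / ACAT-O.** The Cauchy combination uses the tangent asymptote
`w_j/(p_j pi)` for p below 1e-15 and truncates p ≥ 1 − 1e-15; for combined
statistics above 1e15 the arctan is replaced by its Cauchy-tail asymptote
to avoid returning zero. ACAT-V weights are `w_j² maf_j(1−maf_j)`;
ACAT-O combines the three method p-values with equal weights (no weighting
is prescribed by the analysis design).

The Cauchy combination is exactly valid only under independence or in the
tail; under strong positive exchangeable dependence its bulk distribution
is measurably non-uniform. Under the generator's AR(1) blocks and the
MAF-based weights the deviation is negligible (empirical CDF gap < 0.01),
which is what the calibration test certifies — a claim about these study
conditions, not about arbitrary LD.

## Polygene pruning

Only candidate genes — minimum single-method p below 2.5×10⁻⁵ in any
scenario — are pruned. Rivals are SNPs within ±500 kb of the gene body but
outside it; a within-gene SNP is excluded iff some rival has a strictly
smaller GWAS p-value and r² strictly above 0.5, the reported rival being
the qualifying one with maximal r². The pass is single (exclusions remove
only within-gene SNPs, so rival ordering never changes). Window, r²
threshold and single-pass behavior are configurable and recorded in output
headers; the exact constants of the original procedure are not public, so
these defaults follow common conditional-analysis practice. After pruning
the gene tests are re-run on the retained SNPs; identification applies the
strict ACAT-O p < 2.5×10⁻⁵ rule per scenario, and the final gene list is
the union over scenarios.

## Downstream stages

*Pathogenicity*: a coding variant (exonic/nonsynonymous SNPs with GWAS
p < 0.05 in genes identified under a protein-coding scenario) is
`pathogenic` if any of SIFT < 0.05, PolyPhen > 0.5, FATHMM-XF > 0.5,
CADD phred > 20 (all strict); missing scores never flag; all-missing gives
the distinct status `undetermined`. Scores come from a user-supplied
table; the predictors themselves are out of scope.

*Enrichment*: upper-tail hypergeometric `P(X ≥ overlap)` against an
explicit universe (never defaulted), BH-FDR for pathway sets (q ≤ 0.05)
and Bonferroni for tissue differential-expression sets (adjusted
p < 0.05). Adjustment is delegated to `statsmodels.stats.multitest` and
verified in the tests against a hand-rolled step-up oracle.

*SMR/HEIDI*: the instrument is the most significant cis-eQTL SNP inside
the gene body passing p < 5×10⁻⁸. HEIDI test SNPs need r² to the top SNP
inside [0.05, 0.9] and eQTL p < 1.6×10⁻³, at most 20 (by eQTL
significance), at least 3 (otherwise the probe is untested, a distinct
status that never supports a pleiotropy claim). The ratio estimates
`b_SMR(i) = b_GWAS(i)/b_eQTL(i)` get first-order delta-method variances
and LD-derived covariances; `T_HEIDI = sum z_d²` is referred to the
weighted chi-square mixture with the eigenvalues of the z_d correlation
matrix. Verdicts: pleiotropy iff SMR significant (BH-adjusted across
probes, alpha 0.05) *and* p_HEIDI ≥ 0.01; linkage iff SMR significant and
p_HEIDI < 0.01. These constants follow the published SMR methodology and
are config-exposed.

## Synthetic-data generator

Haplotypes follow a latent-Gaussian threshold model: block-correlated
standard normals dichotomized at the allele-frequency quantile; dosage =
sum of two independent haplotypes. The dosage correlation of two SNPs is
then available in closed form (standardized bivariate-normal orthant
probability), which the tests use as an independent oracle. Within-block
latent correlation is AR(1) by default (LD decays with distance along a
chromosome; exchangeable blocks are available as an option), with
`ld_block_rho = 0.5` and MAF uniform on (0.01, 0.5) — a common-variant
GWAS regime. Genes (default 100) are tiled at 400 kb spacing with 6–10
SNPs across a 60 kb body, intergenic SNPs between them, and a configurable
number of injected records violating the MAF/INFO floors so QC is
exercised.

The phenotype is a continuous Gaussian trait `y = sum beta_c g_c + e` with
per-causal-SNP heritability 0.002 (marginal non-centrality n·h² = 40 at
the default n = 20,000 — a clearly detectable GWAS signal); a sum-score
trait behaves identically at the level of summary statistics, which is all
the analysis consumes. Marginal least-squares regressions give beta/se;
p-values are two-sided normal, so beta, se and p are mutually consistent
by construction. Reported MAF is the cohort's empirical frequency; INFO is
drawn from [0.85, 1].

*Shadow genes* carry no causal SNP; their whole block, including one
external "hit" SNP 50 kb past the gene end, is exchangeable at latent
rho 0.99 with a shared allele frequency, giving dosage r² ≈ 0.82 between
gene SNPs and the hit. The hit's effect is 3× the base per-SNP
heritability. Both constants come from a design analysis of the pruning
comparison: a tagging SNP escapes exclusion when its z-score exceeds the
hit's, an event of probability ≈ Phi(−sqrt((1−r)/2)·z_hit), so r barely
above the tagging floor together with a dominant hit makes shadow survival
rare (~1% per gene) while keeping the scenario honest.

*eQTL scenarios*: pleiotropy probes share the trait-causal SNP; linkage
probes are driven by a neighboring SNP of the same block. The stand-alone
SMR locus generator uses 20 SNPs under latent AR(1) 0.95 (adjacent dosage
r² ≈ 0.6, the linkage condition), a top-hit-scale GWAS signal (per-locus
h² 0.008, z ≈ 12 at n = 20,000) and a blood-eQTL-scale expression cohort
(n = 5,000, cis h² 0.04). Loci analyzed by SMR in practice are exactly
such top hits; at substantially weaker signals HEIDI has little power and
most linkage loci would (correctly, given the data) not be distinguished.

`null_zscore_genes` draws `z ~ N(0, R)` directly — the exact sampling
distribution of a null gene's summary statistics — so calibration studies
with thousands of genes avoid genotype-level cost.

What the generator does *not* emulate: realistic human LD maps and allele
frequency spectra, imputation error structure (INFO is decorative),
population stratification, binary traits, allele-coding mismatches between
cohorts, and overlapping genes. Passing tests therefore certify the
statistical machinery under the stated model, not robustness to those
real-data complications.

## Problem sizes and determinism

The test suite runs the calibration study at 2,000 null genes (8 SNPs
each, AR(1) rho 0 and 0.5), the pruning study at n = 20,000 with 100 genes
(10 causal, 10 shadow at r² ≥ 0.8 within 200 kb, 80 null), SKAT-O
Monte-Carlo comparisons at 10⁶ replicates, and 500 SMR replicates per
scenario; `scripts/acceptance.py` uses 800 calibration genes and 150 SMR
replicates per scenario. These sizes give comfortable Monte-Carlo margins
for every bound they are checked against.

All randomness flows through explicitly passed seeds; the pipeline itself
is deterministic given its inputs, and result tables are written with
fixed float formatting plus headers recording the package version, a hash
of the analysis parameters (paths excluded) and the seed — two runs with
the same inputs and seed are byte-identical.

## Known limitations

* The exact SKAT-O omnibus integration assumes the per-rho statistics are
  exchangeable through the burden/orthogonal decomposition; with fewer
  than ~2 SNPs or a burden-degenerate Phi it degrades gracefully to
  closed forms or the Bonferroni bound.
* HEIDI uses first-order delta-method variances; with weak instruments
  (|z_eQTL| barely above the sub-threshold) the ratio distribution is
  heavy-tailed and the test is known to be slightly anticonservative.
* The Cauchy combination's bulk calibration under strong exchangeable
  positive dependence is approximate (see above); tail validity, which
  drives the 2.5×10⁻⁵ identification rule, is unaffected.
* Allele harmonization flips effect signs by identifier and allele match
  only; strand-ambiguous A/T and C/G SNPs are retained as-is and no
  frequency-based inference is attempted.
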