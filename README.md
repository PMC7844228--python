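# polygene

Gene-based association analysis of a quantitative trait from GWAS summary
statistics, with **polygene pruning** — a procedure that strips a gene of
association signal borrowed, through linkage disequilibrium (LD), from
stronger GWAS hits outside the gene — plus downstream pathogenicity
classification, gene-set enrichment and SMR/HEIDI pleiotropy analysis.

## The problem

Genome-wide association studies report per-SNP marginal effects
(`beta_j`, `se_j`, p-values). Gene-based tests aggregate those signals over
all SNPs in a gene region, gaining power for genes whose effect is spread
over several variants. Two things complicate the interpretation:

1. a "significant" gene may merely *tag* a strong GWAS peak outside its
   body — its SNPs are in high LD with the true signal; and
2. the functional route matters: association carried by protein-coding
   variants (which alter the protein) means something different from
   association carried by intronic/UTR variants (which act through
   regulation).

`polygene` addresses both. Each gene is tested under four SNP scenarios
(**all** within-gene SNPs, **non-coding** = introns + 5'/3' UTRs,
**exonic**, **nonsynonymous**); candidate genes are then re-tested after
excluding every within-gene SNP that is in high LD (r² > 0.5 by default)
with a more significant SNP outside the gene. Genes identified through the
coding scenarios feed a variant-pathogenicity stage; genes identified
through non-coding scenarios feed a summary-based Mendelian randomization
(SMR) stage against eQTL data, with the HEIDI test separating pleiotropy
from linkage.

## The statistics

With `z = beta/se` the vector of SNP z-scores in a gene and `R` the
genotype correlation (LD) matrix estimated from a reference panel,
`z ~ N(0, R)` under the null. Three tests are computed per gene/scenario,
with Beta(MAF; 1, 25) SNP weights `W`:

* **SKAT-O** — `Q_rho = z' W^{1/2} [(1-rho)I + rho 11'] W^{1/2} z`,
  minimized over a grid of the mixing parameter `rho` (rho = 0: SKAT
  variance component; rho = 1: burden). The omnibus p-value
  `P(min_rho p_rho < T_obs)` is computed essentially exactly by
  conditioning on the burden component, not by the usual moment-matched
  approximation.
* **PCA** — `T = sum_{i<=k} (q_i' z)^2 / lambda_i ~ chi2_k`, with `k` the
  smallest number of principal components of `R` explaining 85% of the
  variance.
* **ACAT-V** — the weighted Cauchy combination
  `T = sum w_j tan((0.5 - p_j) pi) / sum w_j` of per-SNP p-values.

The three are combined per gene and scenario with an equal-weight Cauchy
combination (**ACAT-O**). Candidate genes (any single-method
p < 2.5×10⁻⁵) are pruned and re-tested; a gene is **identified** when its
post-pruning ACAT-O p-value is below 2.5×10⁻⁵ in at least one scenario.

Tail probabilities of the quadratic forms `sum lambda_i chi2_1` behind
SKAT-type statistics are computed by Imhof characteristic-function
inversion, switching to exact contour (steepest-descent) inversion in the
deep tail, with a Liu moment-matching fallback.

For the SMR stage, `b_SMR = b_GWAS / b_eQTL` at the top cis-eQTL SNP,
`T_SMR = z_G² z_E² / (z_G² + z_E²) ~ chi2_1`, and HEIDI refers the summed
squared standardized differences `b_SMR(i) − b_SMR(top)` over LD-linked
SNPs to their joint null distribution.

## A worked example

The synthetic-data generator plants genes with known causal architecture,
including "shadow" genes whose only signal is LD with an external hit:

```bash
python examples/03_polygene_pruning.py
```

```text
truth: causal = ['GENE004', 'GENE005', 'GENE006', 'GENE009']  shadow = ['GENE001', 'GENE010']
identified without pruning: ['GENE001', 'GENE004', 'GENE005', 'GENE006', 'GENE009', 'GENE010']
identified with pruning:    ['GENE004', 'GENE005', 'GENE006', 'GENE009']
22 SNP exclusions; example decisions:
gene_id scenario   snp_id rival_snp_id       r2     p_within      p_rival  excluded
GENE001      all rs000001     rs000007 0.846739 7.059385e-18 3.813006e-21         1
```

Without pruning, both shadow genes pass the identification threshold on
borrowed signal; every one of their SNPs tags a more significant external
rival at r² ≈ 0.84, so pruning removes them and the re-test discards the
genes. The per-scenario tests on a causal-coding gene
(`examples/02_gene_tests.py`) show the functional resolution:

```text
GENE004: 6 SNPs; causal: ['rs000026', 'rs000029']
  all            m=6  SKAT-O=6.70e-01 (rho*=0.00)  PCA=4.44e-14 (k=5)  ACAT-V=7.49e-09  ACAT-O=1.33e-13
  noncoding      m=3  SKAT-O=9.23e-01 (rho*=0.00)  PCA=2.59e-02 (k=3)  ACAT-V=9.84e-01  ACAT-O=9.19e-01
  exonic         m=3  SKAT-O=1.78e-09 (rho*=0.00)  PCA=2.99e-20 (k=3)  ACAT-V=5.33e-13  ACAT-O=8.96e-20
  nonsynonymous  m=2  SKAT-O=1.75e-09 (rho*=0.00)  PCA=1.33e-20 (k=2)  ACAT-V=5.33e-13  ACAT-O=3.98e-20
```

The association concentrates in the coding scenarios — exactly where the
generator planted the effects — while the non-coding set is null.
`examples/05_smr_heidi.py` shows the SMR stage calling *pleiotropy*
(p_HEIDI = 0.82) when trait and expression share a causal variant and
*linkage* (p_HEIDI = 0.0024) when two causal variants sit in LD at
r² ≈ 0.6.

A thin CLI wraps the same pipeline: `polygene simulate`, `polygene run
--config pipeline.yaml`, plus `test`, `prune`, `downstream` and `smr`
subcommands for partial runs.

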