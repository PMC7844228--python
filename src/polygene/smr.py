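"""Summary-data-based Mendelian randomization (SMR) with the HEIDI test.

For a gene expression trait (probe) with a strong cis-eQTL, SMR asks whether
the GWAS trait association at the locus is mediated by / pleiotropic with
expression: with the top eQTL SNP as instrument,

    b_SMR = b_GWAS / b_eQTL,
    T_SMR = z_GWAS^2 z_eQTL^2 / (z_GWAS^2 + z_eQTL^2) ~ chi2_1 under H0.

A significant SMR p-value is compatible with both a single shared causal
variant (pleiotropy) and two distinct causal variants in LD (linkage).  The
HEIDI test separates them: under the single-variant hypothesis the ratio
estimate b_SMR(i) is the same at every SNP i in LD with the top SNP, so the
standardized differences d_i = b_SMR(i) - b_SMR(top) have mean zero and

    T_HEIDI = sum_i z_{d_i}^2

follows a weighted chi-square mixture with weights from the correlation
matrix of the z_d (delta-method variances, LD-derived covariances).  A locus
with significant SMR and non-small HEIDI p is called pleiotropy; significant
SMR with small HEIDI p is called linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .downstream import adjust
from .quadform import P_FLOOR, quadform_pvalue

__all__ = [
    "EqtlRecord",
    "SmrResult",
    "read_eqtl",
    "smr_test",
    "heidi_test",
    "classify_locus",
    "smr_locus",
    "smr_analysis",
]

INSTRUMENT_P = 5e-8        # top eQTL SNP must pass this to instrument
HEIDI_EQTL_P = 1.6e-3      # test SNPs need this sub-threshold eQTL signal
HEIDI_R2_WINDOW = (0.05, 0.9)
HEIDI_MAX_SNPS = 20
HEIDI_FLOOR = 0.01
HEIDI_MIN_SNPS = 3


@dataclass
class EqtlRecord:
    snp_id: str
    probe_id: str
    beta_eqtl: float
    se_eqtl: float
    p_eqtl: float

    def __post_init__(self):
        if self.se_eqtl <= 0:
            raise ValueError("eQTL standard error must be positive")


@dataclass
class SmrResult:
    probe_id: str
    top_snp: str
    b_smr: float
    p_smr: float
    p_heidi: float | None     # None = untested (too few eligible SNPs)
    n_heidi_snps: int
    verdict: str = "not_significant"
    p_smr_adj: float = np.nan


def read_eqtl(path, sep="\t") -> pd.DataFrame:
    """eQTL summary statistics TSV: probe_id, snp_id, beta_eqtl, se_eqtl, p_eqtl."""
    df = pd.read_csv(path, sep=sep, dtype={"probe_id": str, "snp_id": str},
                     comment="#")
    required = ["probe_id", "snp_id", "beta_eqtl", "se_eqtl", "p_eqtl"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"eQTL file is missing columns: {missing}")
    if (df["se_eqtl"] <= 0).any():
        raise ValueError("eQTL standard errors must be positive")
    return df[required].copy()


def smr_test(z_gwas: float, z_eqtl: float, b_gwas: float, b_eqtl: float):
    """SMR effect and p-value at a single instrument SNP.

    Returns (b_smr, p_smr) with b_smr = b_gwas / b_eqtl and
    T_smr = z_g^2 z_e^2 / (z_g^2 + z_e^2) referred to chi2_1.
    """
    if b_eqtl == 0:
        raise ValueError("cannot instrument with a zero eQTL effect")
    zg2, ze2 = z_gwas ** 2, z_eqtl ** 2
    denom = zg2 + ze2
    t = zg2 * ze2 / denom if denom > 0 else 0.0
    p = float(np.clip(stats.chi2.sf(t, 1), P_FLOOR, 1.0))
    return b_gwas / b_eqtl, p


def heidi_test(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    ld,
    top_snp: str,
    r2_window=HEIDI_R2_WINDOW,
    max_snps: int = HEIDI_MAX_SNPS,
    eqtl_p_max: float = HEIDI_EQTL_P,
):
    """Heterogeneity in dependent instruments at one locus.

    ``gwas``/``eqtl`` are aligned per-SNP tables (canonical columns; eqtl
    restricted to one probe); ``ld`` is an io.LDMatrix covering the locus.
    Test SNPs are those, besides the top SNP, with r2 to it inside
    ``r2_window`` and eQTL p below ``eqtl_p_max``; they are capped at
    ``max_snps`` by smallest eQTL p.  Returns (p_heidi, n_used), with
    p_heidi None when fewer than three SNPs are eligible.
    """
    g = gwas.set_index("snp_id")
    e = eqtl.set_index("snp_id")
    common = [s for s in g.index if s in e.index and s in ld.snp_ids]
    if top_snp not in common:
        raise ValueError("top SNP absent from the aligned locus tables")
    lo, hi = r2_window
    cands = [
        s for s in common
        if s != top_snp
        and lo <= ld.r2(s, top_snp) <= hi
        and e.loc[s, "p_eqtl"] < eqtl_p_max
    ]
    if len(cands) < HEIDI_MIN_SNPS:
        return None, len(cands)
    cands.sort(key=lambda s: e.loc[s, "p_eqtl"])
    cands = cands[:max_snps]

    snps = [top_snp] + cands
    bg = g.loc[snps, "beta"].to_numpy(float)
    sg = g.loc[snps, "se"].to_numpy(float)
    be = e.loc[snps, "beta_eqtl"].to_numpy(float)
    se = e.loc[snps, "se_eqtl"].to_numpy(float)
    if np.any(be == 0):
        raise ValueError("zero eQTL effect among HEIDI SNPs")
    r = ld.submatrix(snps)

    bxy = bg / be
    # first-order (delta method) covariance of the ratio estimates:
    # cov(bxy_i, bxy_j) = bxy_i bxy_j [ r_ij sg_i sg_j / (bg_i bg_j)
    #                                  + r_ij se_i se_j / (be_i be_j) ]
    gw = sg / bg
    ew = se / be
    cov = np.outer(bxy, bxy) * (r * np.outer(gw, gw) + r * np.outer(ew, ew))
    d = bxy[1:] - bxy[0]
    cov_d = cov[1:, 1:] - cov[1:, [0]] - cov[[0], 1:] + cov[0, 0]
    sd = np.sqrt(np.clip(np.diag(cov_d), 1e-300, None))
    z_d = d / sd
    corr = cov_d / np.outer(sd, sd)
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)
    t_heidi = float(np.sum(z_d ** 2))
    lam = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
    p = quadform_pvalue(lam, t_heidi) if t_heidi > 0 else 1.0
    return float(p), len(cands)


def classify_locus(res: SmrResult, smr_alpha: float = 0.05,
                   heidi_floor: float = HEIDI_FLOOR) -> str:
    """pleiotropy / linkage / not_significant verdict for one probe.

    Uses the multiplicity-adjusted SMR p-value when present.  An untested
    HEIDI (too few SNPs) cannot support a pleiotropy claim and yields
    not_significant.
    """
    p_adj = res.p_smr_adj if np.isfinite(res.p_smr_adj) else res.p_smr
    if not p_adj < smr_alpha:
        return "not_significant"
    if res.p_heidi is None:
        return "not_significant"
    return "pleiotropy" if res.p_heidi >= heidi_floor else "linkage"


def smr_locus(
    probe_id: str,
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    ld,
    gene=None,
    instrument_p: float = INSTRUMENT_P,
    **heidi_kw,
) -> SmrResult | None:
    """SMR + HEIDI for one probe at one locus.

    The instrument is the most significant eQTL SNP (restricted to the gene
    body when ``gene`` is given); returns None when no SNP passes the
    instrument threshold.
    """
    e = eqtl.loc[eqtl["probe_id"] == probe_id]
    g = gwas.set_index("snp_id")
    e = e.loc[e["snp_id"].isin(g.index) & e["snp_id"].isin(ld.snp_ids)]
    cand = e
    if gene is not None:
        inside = gwas.loc[
            (gwas["chrom"].astype(str) == str(gene["chrom"]))
            & (gwas["pos"] >= int(gene["tx_start"]))
            & (gwas["pos"] <= int(gene["tx_end"])), "snp_id"]
        cand = e.loc[e["snp_id"].isin(set(inside))]
    cand = cand.loc[cand["p_eqtl"] < instrument_p]
    if cand.empty:
        return None
    top = cand.sort_values("p_eqtl").iloc[0]
    top_snp = str(top["snp_id"])
    zg = float(g.loc[top_snp, "beta"] / g.loc[top_snp, "se"])
    ze = float(top["beta_eqtl"] / top["se_eqtl"])
    b_smr, p_smr = smr_test(zg, ze, float(g.loc[top_snp, "beta"]),
                            float(top["beta_eqtl"]))
    p_heidi, n_used = heidi_test(gwas, e, ld, top_snp, **heidi_kw)
    return SmrResult(
        probe_id=probe_id,
        top_snp=top_snp,
        b_smr=b_smr,
        p_smr=p_smr,
        p_heidi=p_heidi,
        n_heidi_snps=n_used,
    )


def smr_analysis(results: list[SmrResult], smr_alpha: float = 0.05,
                 heidi_floor: float = HEIDI_FLOOR,
                 adjust_method: str = "bh") -> list[SmrResult]:
    """Adjust SMR p-values across probes (BH by default) and set verdicts."""
    if not results:
        return results
    padj = adjust([r.p_smr for r in results], method=adjust_method)
    for r, pa in zip(results, padj):
        r.p_smr_adj = float(pa)
        r.verdict = classify_locus(r, smr_alpha, heidi_floor)
    return results
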