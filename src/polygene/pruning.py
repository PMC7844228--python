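"""Polygene pruning: remove within-gene SNPs whose signal is borrowed, via
LD, from stronger GWAS signals outside the gene, then re-test the gene.

A gene-level association can be inflated by a strong GWAS hit outside the
gene if within-gene SNPs tag it.  The procedure, applied only to candidate
genes (any gene-based method p below a threshold, 2.5e-5 by default):

1. collect *rival* SNPs — outside the gene body but within ``window_kb`` of
   it on the same chromosome;
2. exclude every within-gene SNP s for which some rival e has a smaller
   GWAS p-value and r^2(s, e) above ``r2_threshold`` (single pass; the
   reported rival is the qualifying one with maximal r^2);
3. re-run the gene-based tests on the remaining SNPs; the gene is
   *identified* if the post-pruning combined ACAT-O p-value stays below the
   threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetests import GeneTestResult

__all__ = [
    "PruningDecision",
    "PruningReport",
    "CANDIDATE_THRESHOLD",
    "select_candidates",
    "find_rivals",
    "prune_gene",
    "identify",
]

CANDIDATE_THRESHOLD = 2.5e-5


@dataclass
class PruningDecision:
    snp_id: str
    rival_snp_id: str | None
    r2: float
    p_within: float
    p_rival: float
    excluded: bool


@dataclass
class PruningReport:
    gene_id: str
    scenario: str
    decisions: list[PruningDecision]
    result_before: GeneTestResult
    result_after: GeneTestResult | None = None

    @property
    def n_before(self) -> int:
        return len(self.decisions)

    @property
    def n_after(self) -> int:
        return sum(not d.excluded for d in self.decisions)

    @property
    def retained_snps(self) -> list[str]:
        return [d.snp_id for d in self.decisions if not d.excluded]


def select_candidates(results, threshold: float = CANDIDATE_THRESHOLD) -> list[str]:
    """Genes whose minimum single-method p-value is below the threshold.

    ``results`` is an iterable of GeneTestResult over genes and scenarios;
    a gene qualifies if min(p_skato, p_pca, p_acatv) < threshold in any
    scenario (strict inequality).  Order of first appearance is kept.
    """
    out: list[str] = []
    for res in results:
        if not res.tested:
            continue
        if min(res.p_skato, res.p_pca, res.p_acatv) < threshold:
            if res.gene_id not in out:
                out.append(res.gene_id)
    return out


def find_rivals(gene, records: pd.DataFrame, window_kb: int = 500) -> list[str]:
    """SNPs within +-window_kb of the gene body but outside it.

    The gene body itself ([tx_start, tx_end]) is never a source of rivals.
    """
    start, end = int(gene["tx_start"]), int(gene["tx_end"])
    w = window_kb * 1000
    sel = (
        (records["chrom"].astype(str) == str(gene["chrom"]))
        & (records["pos"] >= start - w)
        & (records["pos"] <= end + w)
        & ((records["pos"] < start) | (records["pos"] > end))
    )
    return list(records.loc[sel, "snp_id"])


def prune_gene(
    gene_snps: list[str],
    rivals: list[str],
    ld,
    pvalues: dict[str, float],
    r2_threshold: float = 0.5,
) -> list[PruningDecision]:
    """Single-pass exclusion decisions for one gene/scenario SNP set.

    ``ld`` is an io.LDMatrix covering the within-gene SNPs and the rivals
    jointly; ``pvalues`` maps snp_id to its GWAS p-value.  A within-gene SNP
    is excluded iff some rival has a strictly smaller p-value and squared
    correlation strictly above ``r2_threshold``; the recorded rival is the
    qualifying one with the largest r^2.
    """
    decisions = []
    rival_ps = np.array([pvalues[e] for e in rivals]) if rivals else np.empty(0)
    for s in gene_snps:
        p_s = pvalues[s]
        best = None  # (r2, rival, p_rival)
        if rivals:
            r2s = np.array([ld.r2(s, e) for e in rivals])
            ok = (rival_ps < p_s) & (r2s > r2_threshold)
            if ok.any():
                j = int(np.argmax(np.where(ok, r2s, -1.0)))
                best = (float(r2s[j]), rivals[j], float(rival_ps[j]))
        if best is None:
            decisions.append(PruningDecision(s, None, 0.0, p_s, np.nan, False))
        else:
            decisions.append(
                PruningDecision(s, best[1], best[0], p_s, best[2], True)
            )
    return decisions


def identify(result: GeneTestResult | None,
             threshold: float = CANDIDATE_THRESHOLD) -> bool:
    """A gene counts as identified iff its ACAT-O p-value is below threshold."""
    if result is None or not result.tested:
        return False
    return bool(result.p_acato < threshold)


def decisions_frame(report: PruningReport) -> pd.DataFrame:
    """One row per pruning decision, for TSV serialization."""
    return pd.DataFrame(
        {
            "gene_id": report.gene_id,
            "scenario": report.scenario,
            "snp_id": [d.snp_id for d in report.decisions],
            "rival_snp_id": [d.rival_snp_id or "." for d in report.decisions],
            "r2": [d.r2 for d in report.decisions],
            "p_within": [d.p_within for d in report.decisions],
            "p_rival": [d.p_rival for d in report.decisions],
            "excluded": [int(d.excluded) for d in report.decisions],
        }
    )
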