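"""Downstream interpretation: pathogenicity of coding variants and gene-set
enrichment with multiple-testing control.

Pathogenicity follows a fixed four-predictor rule on scores supplied as a
table (SIFT, PolyPhen, FATHMM-XF, CADD; the predictors themselves are never
run here): a variant is pathogenic if at least one method flags it —
SIFT < 0.05, PolyPhen > 0.5, FATHMM-XF > 0.5 or CADD phred > 20, all strict.

Enrichment of a gene list in pre-defined gene sets uses the upper-tail
hypergeometric test against a user-supplied universe, with Benjamini-
Hochberg FDR (q <= 0.05) for pathway sets and Bonferroni (adjusted p < 0.05)
for tissue differential-expression sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PATHOGENICITY_THRESHOLDS",
    "PredictorScores",
    "EnrichmentResult",
    "select_coding_variants",
    "classify_pathogenic",
    "read_scores",
    "read_gmt",
    "hypergeom_enrich",
    "adjust",
]

PATHOGENICITY_THRESHOLDS = {
    "sift": 0.05,        # flagged when strictly below
    "polyphen": 0.5,     # flagged when strictly above
    "fathmm_xf": 0.5,    # flagged when strictly above
    "cadd_phred": 20.0,  # flagged when strictly above
}


@dataclass
class PredictorScores:
    snp_id: str
    sift: float | None = None
    polyphen: float | None = None
    fathmm_xf: float | None = None
    cadd_phred: float | None = None


@dataclass
class EnrichmentResult:
    set_id: str
    overlap: int
    set_size: int
    list_size: int
    universe_size: int
    p: float
    q: float = np.nan


def select_coding_variants(
    identified_genes: list[str],
    scenario_sets,
    records: pd.DataFrame,
    annotations: pd.DataFrame,
    p_max: float = 0.05,
) -> list[str]:
    """Protein-coding SNPs of the identified genes with GWAS p < p_max.

    ``scenario_sets`` maps gene_id to its dict of ScenarioSet (as built by
    regions.build_scenario_sets); coding means the ``exonic`` set, which
    includes all nonsynonymous SNPs.
    """
    classes = dict(zip(annotations["snp_id"], annotations["functional_class"]))
    pvals = dict(zip(records["snp_id"], records["pvalue"]))
    out: list[str] = []
    for gene in identified_genes:
        sets = scenario_sets.get(gene)
        if sets is None:
            continue
        for s in sets["exonic"].snp_ids:
            if s in out:
                continue
            if classes.get(s) in ("nonsynonymous", "exonic_other") and \
                    pvals.get(s, 1.0) < p_max:
                out.append(s)
    return out


def classify_pathogenic(scores: PredictorScores) -> tuple[str, dict[str, bool]]:
    """Apply the four-threshold rule.

    Returns (status, flags); status is ``pathogenic`` if any flag is set,
    ``not_flagged`` if all scores present fail, and ``undetermined`` when no
    score is available at all.  Missing scores never flag.
    """
    flags = {
        "sift": scores.sift is not None
        and scores.sift < PATHOGENICITY_THRESHOLDS["sift"],
        "polyphen": scores.polyphen is not None
        and scores.polyphen > PATHOGENICITY_THRESHOLDS["polyphen"],
        "fathmm_xf": scores.fathmm_xf is not None
        and scores.fathmm_xf > PATHOGENICITY_THRESHOLDS["fathmm_xf"],
        "cadd_phred": scores.cadd_phred is not None
        and scores.cadd_phred > PATHOGENICITY_THRESHOLDS["cadd_phred"],
    }
    present = [
        scores.sift, scores.polyphen, scores.fathmm_xf, scores.cadd_phred
    ]
    if all(v is None for v in present):
        return "undetermined", flags
    return ("pathogenic" if any(flags.values()) else "not_flagged"), flags


def read_scores(path, sep="\t") -> list[PredictorScores]:
    """Scores TSV: snp_id plus sift/polyphen/fathmm_xf/cadd_phred, blanks OK."""
    df = pd.read_csv(path, sep=sep, comment="#")
    if "snp_id" not in df.columns:
        raise KeyError("scores file needs an snp_id column")
    out = []
    for _, row in df.iterrows():
        kw = {}
        for c in ("sift", "polyphen", "fathmm_xf", "cadd_phred"):
            v = row.get(c)
            kw[c] = None if v is None or pd.isna(v) else float(v)
        out.append(PredictorScores(snp_id=str(row["snp_id"]), **kw))
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def hypergeom_enrich(gene_list, gene_set, universe, set_id="set") -> EnrichmentResult:
    """Upper-tail hypergeometric overrepresentation test.

    P(X >= overlap) with population = universe, successes = gene_set
    restricted to the universe, draws = gene_list.  The gene list must be a
    subset of the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_list = set(gene_list)
    if not gene_list <= universe:
        raise ValueError("gene list must be contained in the universe")
    members = set(gene_set) & universe
    overlap = len(gene_list & members)
    n_univ, n_set, n_list = len(universe), len(members), len(gene_list)
    # sf(k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(overlap - 1, n_univ, n_set, n_list))
    return EnrichmentResult(
        set_id=set_id,
        overlap=overlap,
        set_size=n_set,
        list_size=n_list,
        universe_size=n_univ,
        p=min(p, 1.0),
    )


def adjust(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up q-values or Bonferroni.

    Significance is called downstream at q <= 0.05 (BH) or adjusted
    p < 0.05 (Bonferroni).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    raise ValueError(f"unknown adjustment method {method!r}")
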