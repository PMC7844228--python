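"""Assignment of SNPs to genes and construction of the four scenario SNP sets.

A SNP belongs to a gene if its position lies between the gene's transcription
start and stop sites (1-based, inclusive at both ends); a SNP may belong to
several overlapping genes.  Per gene, four nested/disjoint SNP sets are
tested separately:

* ``all``            — every within-gene SNP;
* ``noncoding``      — introns and 5'/3' UTRs;
* ``exonic``         — coding SNPs (nonsynonymous plus other exonic);
* ``nonsynonymous``  — amino-acid-changing substitutions only.

SNPs without an annotation default to ``other_within_gene`` and enter only
the ``all`` set.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import FUNCTIONAL_CLASSES

__all__ = ["SCENARIOS", "ScenarioSet", "assign_snps_to_gene", "build_scenario_sets"]

SCENARIOS = ("all", "noncoding", "exonic", "nonsynonymous")

_SCENARIO_CLASSES = {
    "noncoding": {"intron", "utr5", "utr3"},
    "exonic": {"nonsynonymous", "exonic_other"},
    "nonsynonymous": {"nonsynonymous"},
}


@dataclass
class ScenarioSet:
    gene_id: str
    scenario: str
    snp_ids: list[str]

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


def assign_snps_to_gene(gene, records: pd.DataFrame) -> list[str]:
    """SNP ids with tx_start <= pos <= tx_end on the gene's chromosome.

    ``gene`` is a mapping/row with gene_id, chrom, tx_start, tx_end.  Order
    follows the input records.
    """
    sel = (
        (records["chrom"].astype(str) == str(gene["chrom"]))
        & (records["pos"] >= int(gene["tx_start"]))
        & (records["pos"] <= int(gene["tx_end"]))
    )
    return list(records.loc[sel, "snp_id"])


def build_scenario_sets(gene_id: str, gene_snps: list[str],
                        annotations: pd.DataFrame) -> dict[str, ScenarioSet]:
    """The four scenario SNP sets of one gene.

    ``annotations`` maps snp_id to functional_class; unannotated SNPs count
    as ``other_within_gene``.  Input order is preserved in every set.
    """
    classes = dict(zip(annotations["snp_id"], annotations["functional_class"]))
    unknown = set(classes.values()) - set(FUNCTIONAL_CLASSES)
    if unknown:
        raise ValueError(f"unknown functional classes: {sorted(unknown)}")
    out = {"all": ScenarioSet(gene_id, "all", list(gene_snps))}
    for scenario, wanted in _SCENARIO_CLASSES.items():
        snps = [s for s in gene_snps
                if classes.get(s, "other_within_gene") in wanted]
        out[scenario] = ScenarioSet(gene_id, scenario, snps)
    return out
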