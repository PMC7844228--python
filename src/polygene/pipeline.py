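"""End-to-end orchestration: QC -> gene assignment -> four-scenario gene
tests -> candidate selection -> polygene pruning -> re-test ->
identification -> optional downstream (pathogenicity, enrichment, SMR).

A gene enters the final list if it is identified (post-pruning ACAT-O
p < 2.5e-5 by default) under at least one scenario.  All stages are
deterministic given the input files; every output table carries a header
recording the package version, a hash of the configuration and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import downstream as ds
from . import io, pruning, regions, smr
from .genetests import GeneTestResult, WeightScheme, ZVector, run_gene

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    sumstats: str
    genes: str
    annotations: str
    panel: str
    outdir: str
    eqtl: str | None = None
    scores: str | None = None
    genesets: str | None = None
    dialect: dict = field(default_factory=dict)
    maf_min: float = 0.001
    info_min: float = 0.8
    scenarios: tuple = regions.SCENARIOS
    weight_a: float = 1.0
    weight_b: float = 25.0
    weight_mode: str = "beta_maf"
    var_fraction: float = 0.85
    window_kb: int = 500
    r2_threshold: float = 0.5
    candidate_threshold: float = 2.5e-5
    do_pruning: bool = True
    do_downstream: bool = True
    do_smr: bool = True
    coding_p_max: float = 0.05
    smr_alpha: float = 0.05
    heidi_floor: float = 0.01
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.scenarios = tuple(cfg.scenarios)
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis parameters (input/output paths excluded)."""
        d = asdict(self)
        for key in ("sumstats", "genes", "annotations", "panel", "eqtl",
                    "scores", "genesets", "outdir"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate(self) -> None:
        for name in ("sumstats", "genes", "annotations", "panel"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name in ("eqtl", "scores", "genesets"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if not 0 < self.candidate_threshold < 1:
            raise ValueError("candidate_threshold must lie in (0, 1)")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must lie in [0, 1]")
        bad = set(self.scenarios) - set(regions.SCENARIOS)
        if bad:
            raise ValueError(f"unknown scenarios: {sorted(bad)}")


@dataclass
class PipelineResult:
    gene_tests: pd.DataFrame
    pruning_summary: pd.DataFrame
    pruning_decisions: pd.DataFrame
    identified: pd.DataFrame
    pathogenicity: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    smr_results: pd.DataFrame | None = None

    def identified_genes(self) -> list[str]:
        return list(self.identified["gene_id"])


def _result_row(r: GeneTestResult, stage: str) -> dict:
    return {
        "gene_id": r.gene_id, "scenario": r.scenario, "stage": stage,
        "n_snps": r.n_snps, "p_skato": r.p_skato, "p_pca": r.p_pca,
        "p_acatv": r.p_acatv, "p_acato": r.p_acato, "rho_opt": r.rho_opt,
        "k_pcs": r.k_pcs, "tested": int(r.tested),
    }


def _write(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# polygene {__version__}\n")
        fh.write(f"# config_hash={cfg.config_hash()}\n")
        fh.write(f"# seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full workflow; writes result tables into ``cfg.outdir``."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weights = WeightScheme(cfg.weight_a, cfg.weight_b, cfg.weight_mode)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("load inputs")
        sumstats = io.read_summary_stats(cfg.sumstats, dialect=cfg.dialect)
        genes = io.read_gene_definitions(cfg.genes)
        ann = io.read_annotations(cfg.annotations)
        panel = io.ReferencePanel.load(cfg.panel)
    except Exception as e:
        raise RuntimeError(f"stage 'load inputs' failed: {e}") from e

    stage("quality control")
    sumstats = io.apply_qc_filters(sumstats, cfg.maf_min, cfg.info_min)
    sumstats = io.harmonize_alleles(sumstats, panel)
    in_panel = sumstats["snp_id"].isin(set(panel.snp_ids))
    if (~in_panel).any():
        logger.warning("%d QC-passing SNPs absent from the reference panel",
                       int((~in_panel).sum()))
        sumstats = sumstats.loc[in_panel].reset_index(drop=True)

    stage("gene assignment and gene-based tests")
    pmap = dict(zip(sumstats["snp_id"], sumstats["pvalue"]))
    results: dict[tuple[str, str], GeneTestResult] = {}
    scenario_sets: dict[str, dict] = {}
    gene_ld: dict[str, io.LDMatrix] = {}
    sum_idx = sumstats.set_index("snp_id")
    for _, gene in genes.iterrows():
        gid = gene["gene_id"]
        gene_snps = regions.assign_snps_to_gene(gene, sumstats)
        if not gene_snps:
            continue
        sets = regions.build_scenario_sets(gid, gene_snps, ann)
        scenario_sets[gid] = sets
        ld = io.compute_ld(panel, gene_snps)
        gene_ld[gid] = ld
        for scen in cfg.scenarios:
            snps = sets[scen].snp_ids
            if not snps:
                results[(gid, scen)] = GeneTestResult.untested(gid, scen)
                continue
            sub = sum_idx.loc[snps].reset_index()
            zv = ZVector(snps, (sub["beta"] / sub["se"]).to_numpy(),
                         sub["maf"].to_numpy())
            results[(gid, scen)] = run_gene(
                gid, scen, zv, ld, weights, var_fraction=cfg.var_fraction)

    tests_df = pd.DataFrame(
        [_result_row(r, "pre_pruning") for r in results.values()])

    stage("candidate selection")
    candidates = pruning.select_candidates(
        results.values(), cfg.candidate_threshold)
    logger.info("%d candidate genes below %.3g", len(candidates),
                cfg.candidate_threshold)

    stage("polygene pruning and re-test")
    prune_rows, decision_frames = [], []
    final_results: dict[tuple[str, str], GeneTestResult] = dict(results)
    gene_by_id = genes.set_index("gene_id")
    if cfg.do_pruning:
        for gid in candidates:
            gene = gene_by_id.loc[gid]
            gene = pd.concat([pd.Series({"gene_id": gid}), gene])
            rivals = pruning.find_rivals(gene, sumstats, cfg.window_kb)
            all_snps = scenario_sets[gid]["all"].snp_ids
            joint = io.compute_ld(panel, list(all_snps) + rivals)
            for scen in cfg.scenarios:
                res_before = results[(gid, scen)]
                if not res_before.tested:
                    continue
                snps = scenario_sets[gid][scen].snp_ids
                decisions = pruning.prune_gene(
                    snps, rivals, joint, pmap, cfg.r2_threshold)
                report = pruning.PruningReport(gid, scen, decisions, res_before)
                retained = report.retained_snps
                if retained:
                    sub = sum_idx.loc[retained].reset_index()
                    zv = ZVector(retained,
                                 (sub["beta"] / sub["se"]).to_numpy(),
                                 sub["maf"].to_numpy())
                    res_after = run_gene(gid, scen, zv, gene_ld[gid], weights,
                                         var_fraction=cfg.var_fraction)
                else:
                    res_after = GeneTestResult.untested(gid, scen)
                report.result_after = res_after
                final_results[(gid, scen)] = res_after
                decision_frames.append(pruning.decisions_frame(report))
                prune_rows.append({
                    "gene_id": gid, "scenario": scen,
                    "n_before": report.n_before, "n_after": report.n_after,
                    "p_acato_before": res_before.p_acato,
                    "p_acato_after": res_after.p_acato
                    if res_after.tested else np.nan,
                    "identified": int(pruning.identify(
                        res_after, cfg.candidate_threshold)),
                })

    pruning_summary = pd.DataFrame(
        prune_rows, columns=["gene_id", "scenario", "n_before", "n_after",
                             "p_acato_before", "p_acato_after", "identified"])
    pruning_decisions = (
        pd.concat(decision_frames, ignore_index=True) if decision_frames
        else pd.DataFrame(columns=["gene_id", "scenario", "snp_id",
                                   "rival_snp_id", "r2", "p_within",
                                   "p_rival", "excluded"]))

    stage("identification")
    id_rows = []
    for gid in candidates:
        scens = [s for s in cfg.scenarios
                 if pruning.identify(final_results[(gid, s)],
                                     cfg.candidate_threshold)]
        if scens:
            id_rows.append({
                "gene_id": gid,
                "scenarios": ",".join(scens),
                "protein_coding": int(bool({"exonic", "nonsynonymous"}
                                           & set(scens))),
                "noncoding": int("noncoding" in scens),
                "p_acato_min": min(final_results[(gid, s)].p_acato
                                   for s in scens),
            })
    identified = pd.DataFrame(
        id_rows, columns=["gene_id", "scenarios", "protein_coding",
                          "noncoding", "p_acato_min"])

    result = PipelineResult(
        gene_tests=tests_df,
        pruning_summary=pruning_summary,
        pruning_decisions=pruning_decisions,
        identified=identified,
    )

    if cfg.do_downstream and cfg.scores is not None:
        stage("pathogenicity classification")
        coding_genes = identified.loc[identified["protein_coding"] == 1,
                                      "gene_id"].tolist()
        variants = ds.select_coding_variants(
            coding_genes, scenario_sets, sumstats, ann, cfg.coding_p_max)
        scores = {s.snp_id: s for s in ds.read_scores(cfg.scores)}
        prows = []
        for v in variants:
            sc = scores.get(v)
            if sc is None:
                status, flags = "undetermined", {}
            else:
                status, flags = ds.classify_pathogenic(sc)
            prows.append({
                "snp_id": v, "status": status,
                **{f"flag_{k}": int(bool(f)) for k, f in flags.items()},
            })
        result.pathogenicity = pd.DataFrame(
            prows, columns=["snp_id", "status", "flag_sift", "flag_polyphen",
                            "flag_fathmm_xf", "flag_cadd_phred"])

    if cfg.do_downstream and cfg.genesets is not None:
        stage("gene-set enrichment")
        sets = ds.read_gmt(cfg.genesets)
        universe = genes["gene_id"].tolist()
        glist = identified["gene_id"].tolist()
        erows = []
        for set_id, members in sets.items():
            er = ds.hypergeom_enrich(glist, members, universe, set_id)
            erows.append({
                "set_id": set_id, "overlap": er.overlap,
                "set_size": er.set_size, "list_size": er.list_size,
                "universe_size": er.universe_size, "p": er.p,
            })
        edf = pd.DataFrame(erows, columns=["set_id", "overlap", "set_size",
                                           "list_size", "universe_size", "p"])
        if len(edf):
            edf["q"] = ds.adjust(edf["p"].to_numpy(), "bh")
            edf["p_bonferroni"] = ds.adjust(edf["p"].to_numpy(), "bonferroni")
        result.enrichment = edf

    if cfg.do_smr and cfg.eqtl is not None:
        stage("SMR/HEIDI")
        eqtl = smr.read_eqtl(cfg.eqtl)
        nc_genes = identified.loc[identified["noncoding"] == 1,
                                  "gene_id"].tolist()
        smr_results = []
        for gid in nc_genes:
            gene = gene_by_id.loc[gid]
            gene = pd.concat([pd.Series({"gene_id": gid}), gene])
            gene_snps = scenario_sets[gid]["all"].snp_ids
            probes = eqtl.loc[eqtl["snp_id"].isin(gene_snps),
                              "probe_id"].unique()
            for probe in probes:
                sub_e = eqtl.loc[eqtl["probe_id"] == probe]
                locus_snps = [s for s in sub_e["snp_id"]
                              if s in set(sumstats["snp_id"])]
                if len(locus_snps) < 2:
                    continue
                ld = io.compute_ld(panel, locus_snps)
                res = smr.smr_locus(probe, sumstats, eqtl, ld, gene=gene)
                if res is not None:
                    res.probe_id = probe
                    smr_results.append((gid, res))
        smr.smr_analysis([r for _, r in smr_results], cfg.smr_alpha,
                         cfg.heidi_floor)
        result.smr_results = pd.DataFrame([
            {"gene_id": gid, "probe_id": r.probe_id, "top_snp": r.top_snp,
             "b_smr": r.b_smr, "p_smr": r.p_smr, "p_smr_adj": r.p_smr_adj,
             "p_heidi": np.nan if r.p_heidi is None else r.p_heidi,
             "n_heidi_snps": r.n_heidi_snps, "verdict": r.verdict}
            for gid, r in smr_results],
            columns=["gene_id", "probe_id", "top_snp", "b_smr", "p_smr",
                     "p_smr_adj", "p_heidi", "n_heidi_snps", "verdict"])

    stage("write outputs")
    _write(result.gene_tests, outdir / "gene_tests.tsv", cfg)
    _write(result.pruning_summary, outdir / "pruning_summary.tsv", cfg)
    _write(result.pruning_decisions, outdir / "pruning_decisions.tsv", cfg)
    _write(result.identified, outdir / "identified_genes.tsv", cfg)
    if result.pathogenicity is not None:
        _write(result.pathogenicity, outdir / "pathogenicity.tsv", cfg)
    if result.enrichment is not None:
        _write(result.enrichment, outdir / "enrichment.tsv", cfg)
    if result.smr_results is not None:
        _write(result.smr_results, outdir / "smr.tsv", cfg)
    return result
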