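"""Synthetic GWAS/eQTL data with known causal architecture.

One synthetic chromosome carries protein-coding genes tiled at a fixed
spacing, each with its own LD block, plus intergenic SNPs between genes.
Haplotypes follow a latent-Gaussian threshold model: within a block, latent
normals with AR(1) (default) or exchangeable correlation are dichotomized at
the allele-frequency quantile, and dosages are sums of two independent
haplotypes.  The model is simple but has closed-form expectations (the
dosage correlation of two SNPs is the standardized bivariate-normal orthant
probability), which the tests exploit.

Gene kinds:

* ``causal_coding``     — nonsynonymous SNPs carry trait effects;
* ``causal_regulatory`` — intronic/UTR SNPs carry trait effects;
* ``shadow_ld``         — no within-gene effect, but every gene SNP is in
  high LD (r^2 ~ 0.82) with an *external* causal hit just outside the gene:
  the configuration the polygene-pruning stage must recognize and discard;
* ``null``              — no effects anywhere nearby.

A quantitative phenotype ``y = sum_c beta_c g_c + e`` is simulated at the
configured per-SNP heritability and marginal single-SNP least-squares
summary statistics (beta, se, two-sided normal p, empirical MAF, INFO drawn
from [0.85, 1]) are emitted — beta/se/p are mutually consistent by
construction.  The generator also injects a configurable number of records
violating the MAF/INFO QC floors, which the QC stage must remove.

eQTL summary statistics for SMR come either from probes attached to the
simulated genes (pleiotropy: expression driven by the trait-causal SNP;
linkage: by a different SNP of the same block) or from the stand-alone
single-locus generator ``simulate_smr_locus``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ReferencePanel, compute_ld

__all__ = [
    "EffectScenario",
    "EqtlScenarioConfig",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_panel",
    "simulate_gwas",
    "simulate_eqtl",
    "simulate_smr_locus",
    "null_zscore_genes",
    "make_fixture_suite",
]

DEFAULT_CLASS_FRACTIONS = {
    "nonsynonymous": 0.08,
    "exonic_other": 0.07,
    "utr5": 0.05,
    "utr3": 0.10,
    "intron": 0.65,
    "other_within_gene": 0.05,
}

_NONCODING = ("intron", "utr5", "utr3")
_ALLELES = ("A", "C", "G", "T")


@dataclass
class EffectScenario:
    kind: str                    # causal_coding | causal_regulatory | shadow_ld | null
    count: int
    h2_per_snp: float | None = None   # None: use the config-wide default
    n_causal_snps: int = 2

    def __post_init__(self):
        if self.kind not in ("causal_coding", "causal_regulatory",
                             "shadow_ld", "null"):
            raise ValueError(f"unknown effect scenario kind {self.kind!r}")


@dataclass
class EqtlScenarioConfig:
    n_individuals: int = 2000
    h2_eqtl: float = 0.04        # expression variance from the causal eQTL


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults emulate a common-variant quantitative-trait GWAS: n = 20,000
    individuals, per-causal-SNP heritability 0.002 (marginal non-centrality
    n*h2 = 40, a clearly detectable single-SNP signal), AR(1) LD decay
    within blocks, and MAF drawn uniformly from (0.01, 0.5).
    """

    n_individuals: int = 20_000
    n_genes: int = 100
    snps_per_gene: tuple[int, int] = (6, 10)
    ld_block_rho: float = 0.5
    ld_structure: str = "ar1"          # or "exchangeable"
    maf_range: tuple[float, float] = (0.01, 0.5)
    class_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    effect_scenarios: list[EffectScenario] = field(
        default_factory=lambda: [
            EffectScenario("causal_coding", 1),
            EffectScenario("causal_regulatory", 1),
            EffectScenario("shadow_ld", 1),
        ])
    heritability_per_causal_snp: float = 0.002
    eqtl: EqtlScenarioConfig = field(default_factory=EqtlScenarioConfig)
    # shadow-gene geometry: latent rho 0.99 at a shared allele frequency
    # puts the dosage-scale r^2 between gene SNPs and the external hit
    # around 0.82; the hit carries a clearly stronger effect than its tags
    # (the scenario being modelled is a gene next to a strong GWAS peak)
    shadow_latent_rho: float = 0.99
    shadow_hit_offset_bp: int = 50_000
    shadow_hit_h2_factor: float = 3.0
    gene_span_bp: int = 60_000
    gene_spacing_bp: int = 400_000
    n_intergenic_per_gap: int = 2
    n_qc_fail_maf: int = 3
    n_qc_fail_info: int = 3
    chrom: str = "1"

    def validate(self) -> None:
        total = sum(self.class_fractions.get(k, 0.0)
                    for k in DEFAULT_CLASS_FRACTIONS)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        n_special = sum(s.count for s in self.effect_scenarios)
        if n_special > self.n_genes:
            raise ValueError("effect-scenario counts exceed n_genes")
        if not (0.0 <= self.ld_block_rho < 1.0):
            raise ValueError("ld_block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")


@dataclass
class _Block:
    """Latent-correlation block: SNP row indices + frequencies + structure."""
    snp_idx: list[int]
    freqs: np.ndarray
    structure: str       # "ar1" | "exchangeable"
    rho: float

    def latent_corr(self) -> np.ndarray:
        k = len(self.snp_idx)
        if self.structure == "ar1":
            return self.rho ** np.abs(np.subtract.outer(np.arange(k),
                                                        np.arange(k)))
        c = np.full((k, k), self.rho)
        np.fill_diagonal(c, 1.0)
        return c


@dataclass
class _Layout:
    snps: pd.DataFrame          # snp_id, pos, freq, gene_id, class, role
    genes: pd.DataFrame         # gene_id, name, chrom, tx_start, tx_end, kind
    blocks: list[_Block]
    chrom: str


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset, for recovery checks."""

    seed: int
    gene_kinds: dict[str, str]
    causal_snps: dict[str, list[str]]        # per causal gene
    external_hits: dict[str, str]            # shadow gene -> causal hit SNP
    hit_h2: dict[str, float]                 # causal SNP/hit -> per-SNP h2
    qc_fail_snps: list[str]
    eqtl_probes: dict[str, dict] = field(default_factory=dict)
    layout: _Layout | None = None

    def causal_genes(self) -> list[str]:
        return [g for g, k in self.gene_kinds.items()
                if k in ("causal_coding", "causal_regulatory")]

    def shadow_genes(self) -> list[str]:
        return [g for g, k in self.gene_kinds.items() if k == "shadow_ld"]

    def null_genes(self) -> list[str]:
        return [g for g, k in self.gene_kinds.items() if k == "null"]

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "gene_kinds": self.gene_kinds,
            "causal_snps": self.causal_snps,
            "external_hits": self.external_hits,
            "hit_h2": self.hit_h2,
            "qc_fail_snps": self.qc_fail_snps,
            "eqtl_probes": self.eqtl_probes,
        }


def _build_layout(cfg: SimulationConfig, rng: np.random.Generator) -> _Layout:
    cfg.validate()
    kinds = []
    for sc in cfg.effect_scenarios:
        kinds += [sc.kind] * sc.count
    kinds += ["null"] * (cfg.n_genes - len(kinds))
    kinds = [kinds[i] for i in rng.permutation(len(kinds))]

    class_names = list(DEFAULT_CLASS_FRACTIONS)
    class_p = np.array([cfg.class_fractions[c] for c in class_names])
    lo_m, hi_m = cfg.snps_per_gene

    rows = []          # snp records
    gene_rows = []
    blocks: list[_Block] = []
    serial = 0

    def new_snp(pos, freq, gene_id, fclass, role):
        nonlocal serial
        serial += 1
        rows.append({
            "snp_id": f"rs{serial:06d}", "pos": int(pos), "freq": float(freq),
            "gene_id": gene_id, "class": fclass, "role": role,
        })
        return len(rows) - 1

    for gi, kind in enumerate(kinds):
        gene_id = f"GENE{gi + 1:03d}"
        tx_start = 1_000_000 + gi * cfg.gene_spacing_bp
        tx_end = tx_start + cfg.gene_span_bp - 1
        gene_rows.append({
            "gene_id": gene_id, "name": gene_id, "chrom": cfg.chrom,
            "tx_start": tx_start, "tx_end": tx_end, "kind": kind,
        })
        m = int(rng.integers(lo_m, hi_m + 1))
        pos = np.sort(rng.choice(cfg.gene_span_bp - 2, size=m, replace=False)) \
            + tx_start + 1
        classes = list(rng.choice(class_names, size=m, p=class_p))
        # causal kinds need enough SNPs of the right class to carry effects
        n_causal = next(
            (sc.n_causal_snps for sc in cfg.effect_scenarios
             if sc.kind == kind), 0)
        if kind == "causal_coding":
            _force_classes(classes, "nonsynonymous", n_causal, rng)
        elif kind == "causal_regulatory":
            _force_classes(classes, "intron", n_causal, rng)

        if kind == "shadow_ld":
            f = float(rng.uniform(0.2, 0.45))
            idx = [new_snp(p, f, gene_id, c, "gene")
                   for p, c in zip(pos, classes)]
            hit = new_snp(tx_end + cfg.shadow_hit_offset_bp, f, None, None,
                          "shadow_hit")
            blocks.append(_Block(idx + [hit], np.full(m + 1, f),
                                 "exchangeable", cfg.shadow_latent_rho))
        else:
            freqs = rng.uniform(*cfg.maf_range, size=m)
            idx = [new_snp(p, f, gene_id, c, "gene")
                   for p, f, c in zip(pos, freqs, classes)]
            blocks.append(_Block(idx, freqs, cfg.ld_structure,
                                 cfg.ld_block_rho))

        # intergenic filler between this gene and the next
        for j in range(cfg.n_intergenic_per_gap):
            p = tx_end + 100_000 + j * 50_000
            f = float(rng.uniform(*cfg.maf_range))
            k = new_snp(p, f, None, None, "intergenic")
            blocks.append(_Block([k], np.array([f]), "ar1", 0.0))

    tail = 1_000_000 + cfg.n_genes * cfg.gene_spacing_bp
    for j in range(cfg.n_qc_fail_maf):
        k = new_snp(tail + j * 1000, 0.0004, None, None, "qc_fail_maf")
        blocks.append(_Block([k], np.array([0.0004]), "ar1", 0.0))
    for j in range(cfg.n_qc_fail_info):
        f = float(rng.uniform(*cfg.maf_range))
        k = new_snp(tail + 100_000 + j * 1000, f, None, None, "qc_fail_info")
        blocks.append(_Block([k], np.array([f]), "ar1", 0.0))

    snps = pd.DataFrame(rows)
    genes = pd.DataFrame(gene_rows)
    return _Layout(snps=snps, genes=genes, blocks=blocks, chrom=cfg.chrom)


def _force_classes(classes: list, wanted: str, n_needed: int,
                   rng: np.random.Generator) -> None:
    have = [i for i, c in enumerate(classes) if c == wanted]
    short = n_needed - len(have)
    if short <= 0:
        return
    others = [i for i, c in enumerate(classes) if c != wanted]
    for i in rng.permutation(others)[:short]:
        classes[int(i)] = wanted


def _draw_dosages(layout: _Layout, n: int, rng: np.random.Generator) -> np.ndarray:
    g = np.zeros((n, len(layout.snps)), dtype=np.int8)
    for block in layout.blocks:
        c = block.latent_corr()
        chol = np.linalg.cholesky(c + 1e-12 * np.eye(len(c)))
        thresh = stats.norm.ppf(block.freqs)
        for _hap in range(2):
            z = rng.standard_normal((n, len(c))) @ chol.T
            g[:, block.snp_idx] += (z < thresh)
    return g


def simulate_panel(cfg: SimulationConfig, seed: int):
    """Genotype panel plus gene/annotation tables and the truth record.

    Returns ``(panel, genes, annotations, truth)``; same seed, same bytes.
    """
    rng = np.random.default_rng(seed)
    layout = _build_layout(cfg, rng)
    dosages = _draw_dosages(layout, cfg.n_individuals, rng)
    panel = ReferencePanel(snp_ids=list(layout.snps["snp_id"]),
                           dosages=dosages.astype(np.float64))

    genes = layout.genes[["gene_id", "name", "chrom", "tx_start", "tx_end"]].copy()
    ann = layout.snps.loc[layout.snps["class"].notna(),
                          ["snp_id", "class"]].rename(
        columns={"class": "functional_class"}).reset_index(drop=True)

    gene_kinds = dict(zip(layout.genes["gene_id"], layout.genes["kind"]))
    causal_snps: dict[str, list[str]] = {}
    external_hits: dict[str, str] = {}
    hit_h2: dict[str, float] = {}
    base_h2 = cfg.heritability_per_causal_snp
    by_gene = layout.snps.groupby("gene_id")
    for _, grow in layout.genes.iterrows():
        gid, kind = grow["gene_id"], grow["kind"]
        sub = by_gene.get_group(gid)
        sc = next((s for s in cfg.effect_scenarios if s.kind == kind), None)
        if kind in ("causal_coding", "causal_regulatory") and sc is not None:
            wanted = ("nonsynonymous",) if kind == "causal_coding" else _NONCODING
            pool = sub.loc[sub["class"].isin(wanted), "snp_id"].tolist()
            chosen = [pool[i] for i in
                      rng.permutation(len(pool))[:sc.n_causal_snps]]
            causal_snps[gid] = sorted(chosen)
            h2 = sc.h2_per_snp if sc.h2_per_snp is not None else base_h2
            for s in chosen:
                hit_h2[s] = h2
        elif kind == "shadow_ld":
            row = layout.snps.loc[layout.snps["role"] == "shadow_hit"]
            # the hit directly following this gene's SNPs
            hit = row.loc[row["pos"] == grow["tx_end"] + cfg.shadow_hit_offset_bp,
                          "snp_id"]
            h2 = (sc.h2_per_snp if sc and sc.h2_per_snp is not None else base_h2)
            external_hits[gid] = str(hit.iloc[0])
            hit_h2[external_hits[gid]] = h2 * cfg.shadow_hit_h2_factor

    truth = SyntheticTruth(
        seed=seed,
        gene_kinds=gene_kinds,
        causal_snps=causal_snps,
        external_hits=external_hits,
        hit_h2=hit_h2,
        qc_fail_snps=layout.snps.loc[
            layout.snps["role"].str.startswith("qc_fail"), "snp_id"].tolist(),
        layout=layout,
    )
    return panel, genes, ann, truth


def _marginal_stats(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-column simple least-squares beta, se and z for phenotype y."""
    n = len(y)
    gm = g.mean(axis=0)
    yc = y - y.mean()
    var_g = g.var(axis=0)
    var_g = np.where(var_g == 0, np.nan, var_g)
    cov = (g * yc[:, None]).mean(axis=0) - gm * 0.0  # y centered: plain mean
    beta = cov / var_g
    ss_res = n * (yc.var() - beta ** 2 * var_g)
    sigma2 = np.maximum(ss_res, 1e-12) / (n - 2)
    se = np.sqrt(sigma2 / (n * var_g))
    beta = np.nan_to_num(beta)
    se = np.where(np.isnan(se), 1.0, se)
    z = beta / se
    return beta, se, z


def simulate_gwas(panel: ReferencePanel, truth: SyntheticTruth,
                  cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    """Marginal summary statistics of the simulated quantitative trait."""
    rng = np.random.default_rng(seed)
    layout = truth.layout
    n = panel.n_individuals

    y = np.zeros(n)
    total_h2 = 0.0
    idx = {s: j for j, s in enumerate(panel.snp_ids)}
    for snp, h2 in sorted(truth.hit_h2.items()):
        gcol = panel.dosages[:, idx[snp]]
        v = gcol.var()
        if v <= 0:
            raise ValueError(f"causal SNP {snp} is monomorphic in the cohort")
        sign = 1.0 if rng.random() < 0.5 else -1.0
        y += sign * np.sqrt(h2 / v) * (gcol - gcol.mean())
        total_h2 += h2
    if total_h2 >= 0.5:
        raise ValueError("total simulated heritability is implausibly large")
    y += rng.standard_normal(n) * np.sqrt(1.0 - total_h2)

    beta, se, z = _marginal_stats(panel.dosages, y)
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    freq_hat = panel.dosages.mean(axis=0) / 2.0
    maf = np.clip(np.minimum(freq_hat, 1.0 - freq_hat), 1.0 / (4.0 * n), 0.5)

    info = rng.uniform(0.85, 1.0, size=len(panel.snp_ids))
    low_info = layout.snps["role"].to_numpy() == "qc_fail_info"
    info[low_info] = rng.uniform(0.5, 0.79, size=low_info.sum())

    ea = rng.choice(_ALLELES, size=len(panel.snp_ids))
    oa = np.array([_ALLELES[(i + 1) % 4] for i in
                   [_ALLELES.index(a) for a in ea]])
    return pd.DataFrame({
        "snp_id": panel.snp_ids,
        "chrom": layout.chrom,
        "pos": layout.snps["pos"].to_numpy(),
        "effect_allele": ea,
        "other_allele": oa,
        "beta": beta,
        "se": se,
        "pvalue": pval,
        "maf": maf,
        "info": info,
    })


def simulate_eqtl(panel: ReferencePanel, truth: SyntheticTruth,
                  cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    """eQTL summary statistics for probes attached to the simulated genes.

    Every causal_regulatory gene gets a *pleiotropy* probe whose expression
    is driven by the gene's first trait-causal SNP; the first regulatory
    gene additionally gets a *linkage* probe driven by a different SNP of
    the same block, and a *null* probe with no genetic effect.  The eQTL
    cohort is drawn independently of the GWAS cohort.
    """
    rng = np.random.default_rng(seed)
    layout = truth.layout
    n_e = cfg.eqtl.n_individuals
    out = []
    reg_genes = [g for g, k in truth.gene_kinds.items()
                 if k == "causal_regulatory"]
    for i, gid in enumerate(sorted(reg_genes)):
        block = _gene_block(layout, gid)
        ids = layout.snps.loc[block.snp_idx, "snp_id"].tolist()
        sub_layout = _Layout(snps=layout.snps.loc[block.snp_idx],
                             genes=layout.genes, chrom=layout.chrom,
                             blocks=[_Block(list(range(len(block.snp_idx))),
                                            block.freqs, block.structure,
                                            block.rho)])
        g = _draw_dosages(sub_layout, n_e, rng).astype(float)
        causal = truth.causal_snps[gid][0]
        jc = ids.index(causal)
        probes = [(f"probe_{gid}", jc, "pleiotropy")]
        if i == 0:
            j_link = jc + 1 if jc + 1 < len(ids) else jc - 1
            probes.append((f"probe_{gid}_linked", j_link, "linkage"))
            probes.append((f"probe_{gid}_null", None, "null"))
        for probe_id, j, kind in probes:
            x = rng.standard_normal(n_e)
            if j is not None:
                gc = g[:, j]
                v = gc.var()
                x = np.sqrt(cfg.eqtl.h2_eqtl / v) * (gc - gc.mean()) \
                    + rng.standard_normal(n_e) * np.sqrt(1 - cfg.eqtl.h2_eqtl)
            beta, se, z = _marginal_stats(g, x)
            pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
            out.append(pd.DataFrame({
                "probe_id": probe_id, "snp_id": ids,
                "beta_eqtl": beta, "se_eqtl": se, "p_eqtl": pval,
            }))
            truth.eqtl_probes[probe_id] = {
                "kind": kind, "gene": gid,
                "causal_snp": None if j is None else ids[j],
            }
    if not out:
        return pd.DataFrame(
            columns=["probe_id", "snp_id", "beta_eqtl", "se_eqtl", "p_eqtl"])
    return pd.concat(out, ignore_index=True)


def _gene_block(layout: _Layout, gene_id: str) -> _Block:
    rows = layout.snps.index[layout.snps["gene_id"] == gene_id].tolist()
    for b in layout.blocks:
        if set(rows) <= set(b.snp_idx):
            return b
    raise KeyError(f"no block found for gene {gene_id}")


def simulate_smr_locus(
    kind: str,
    seed: int,
    n_gwas: int = 20_000,
    n_eqtl: int = 5_000,
    m: int = 20,
    latent_rho: float = 0.95,
    h2_gwas: float = 0.008,
    h2_eqtl: float = 0.04,
    linkage_lag: int = 1,
):
    """One cis locus for SMR/HEIDI benchmarking.

    ``kind`` is ``pleiotropy`` (trait and expression share one causal SNP),
    ``linkage`` (distinct causal SNPs ``linkage_lag`` positions apart,
    dosage r^2 about 0.6 at the default AR(1) latent rho of 0.95) or
    ``null``.  Defaults describe a locus worth following up by SMR: a top
    GWAS hit (per-locus h^2 0.008, z about 12 at n = 20,000) and a
    blood-eQTL-scale expression cohort (n = 5,000, cis h^2 0.04).
    Returns (gwas_df, eqtl_df, ld, gene, truth_dict).
    """
    if kind not in ("pleiotropy", "linkage", "null"):
        raise ValueError(f"unknown SMR scenario {kind!r}")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.1, 0.5, size=m)
    rows = [{"snp_id": f"rs{j + 1:04d}", "pos": 1_000_000 + j * 2_000,
             "freq": freqs[j], "gene_id": "GENE001", "class": "intron",
             "role": "gene"} for j in range(m)]
    layout = _Layout(
        snps=pd.DataFrame(rows),
        genes=pd.DataFrame([{"gene_id": "GENE001", "name": "GENE001",
                             "chrom": "1", "tx_start": 1_000_000,
                             "tx_end": 1_000_000 + 2_000 * m, "kind": kind}]),
        blocks=[_Block(list(range(m)), freqs, "ar1", latent_rho)],
        chrom="1",
    )
    j_eqtl = m // 2
    j_gwas = j_eqtl if kind != "linkage" else j_eqtl + linkage_lag

    g_gwas = _draw_dosages(layout, n_gwas, rng).astype(float)
    y = rng.standard_normal(n_gwas)
    if kind != "null":
        gc = g_gwas[:, j_gwas]
        y = np.sqrt(h2_gwas / gc.var()) * (gc - gc.mean()) \
            + rng.standard_normal(n_gwas) * np.sqrt(1 - h2_gwas)
    beta, se, z = _marginal_stats(g_gwas, y)
    ids = layout.snps["snp_id"].tolist()
    gwas = pd.DataFrame({
        "snp_id": ids, "chrom": "1", "pos": layout.snps["pos"].to_numpy(),
        "effect_allele": "A", "other_allele": "G",
        "beta": beta, "se": se,
        "pvalue": np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
        "maf": np.clip(np.minimum(g_gwas.mean(0) / 2, 1 - g_gwas.mean(0) / 2),
                       1e-6, 0.5),
        "info": 1.0,
    })

    g_e = _draw_dosages(layout, n_eqtl, rng).astype(float)
    x = rng.standard_normal(n_eqtl)
    if kind != "null":
        gc = g_e[:, j_eqtl]
        x = np.sqrt(h2_eqtl / gc.var()) * (gc - gc.mean()) \
            + rng.standard_normal(n_eqtl) * np.sqrt(1 - h2_eqtl)
    beta_e, se_e, z_e = _marginal_stats(g_e, x)
    eqtl = pd.DataFrame({
        "probe_id": "probe_GENE001", "snp_id": ids,
        "beta_eqtl": beta_e, "se_eqtl": se_e,
        "p_eqtl": np.clip(2 * stats.norm.sf(np.abs(z_e)), 1e-300, 1.0),
    })
    panel = ReferencePanel(snp_ids=ids, dosages=g_gwas)
    ld = compute_ld(panel, ids)
    gene = layout.genes.iloc[0]
    truth = {"kind": kind, "eqtl_causal": ids[j_eqtl],
             "gwas_causal": ids[j_gwas] if kind != "null" else None}
    return gwas, eqtl, ld, gene, truth


def null_zscore_genes(n_genes: int, m: int, rho: float, structure: str,
                      rng: np.random.Generator,
                      maf_range=(0.01, 0.5)):
    """Summary-level null genes: z ~ N(0, R) with the block's true R.

    Yields (z, maf, R) per gene — the exact sampling distribution of
    marginal z-scores of a gene with no causal variants, used for
    calibration studies without genotype-level simulation cost.
    """
    if structure == "ar1":
        r = rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    elif structure == "exchangeable":
        r = np.full((m, m), rho)
        np.fill_diagonal(r, 1.0)
    else:
        raise ValueError(f"unknown LD structure {structure!r}")
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(m))
    for _ in range(n_genes):
        z = chol @ rng.standard_normal(m)
        maf = rng.uniform(*maf_range, size=m)
        yield z, maf, r


def fixture_config() -> SimulationConfig:
    """Small configuration for the end-to-end fixture suite (< 30 s)."""
    return SimulationConfig(
        n_individuals=4_000,
        n_genes=12,
        snps_per_gene=(5, 8),
        effect_scenarios=[
            EffectScenario("causal_coding", 2, h2_per_snp=0.008),
            EffectScenario("causal_regulatory", 2, h2_per_snp=0.008),
            EffectScenario("shadow_ld", 2, h2_per_snp=0.008),
        ],
        n_intergenic_per_gap=1,
    )


def make_fixture_suite(seed: int, outdir, cfg: SimulationConfig | None = None):
    """Write a complete small input set plus truth manifest to ``outdir``.

    Files: sumstats.tsv, genes.tsv, annotations.tsv, panel.tsv, eqtl.tsv,
    scores.tsv, genesets.gmt, truth.json.  Returns (paths, truth).
    """
    from pathlib import Path

    cfg = cfg or fixture_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, genes, ann, truth = simulate_panel(cfg, seed)
    gwas = simulate_gwas(panel, truth, cfg, seed + 1)
    eqtl = simulate_eqtl(panel, truth, cfg, seed + 2)
    rng = np.random.default_rng(seed + 3)

    # predictor scores for coding SNPs: trait-causal nonsynonymous variants
    # look damaging, the rest benign; occasional blanks
    coding = ann.loc[ann["functional_class"].isin(
        ("nonsynonymous", "exonic_other")), "snp_id"]
    causal = {s for lst in truth.causal_snps.values() for s in lst}
    srows = []
    for s in coding:
        if s in causal:
            srows.append({"snp_id": s, "sift": 0.01, "polyphen": 0.9,
                          "fathmm_xf": 0.8, "cadd_phred": 25.0})
        else:
            srows.append({"snp_id": s,
                          "sift": round(float(rng.uniform(0.2, 0.9)), 3),
                          "polyphen": round(float(rng.uniform(0.0, 0.4)), 3),
                          "fathmm_xf": "" if rng.random() < 0.2
                          else round(float(rng.uniform(0.0, 0.4)), 3),
                          "cadd_phred": round(float(rng.uniform(0.0, 10.0)), 2)})
    scores = pd.DataFrame(srows)

    paths = {
        "sumstats": outdir / "sumstats.tsv",
        "genes": outdir / "genes.tsv",
        "annotations": outdir / "annotations.tsv",
        "panel": outdir / "panel.tsv",
        "eqtl": outdir / "eqtl.tsv",
        "scores": outdir / "scores.tsv",
        "genesets": outdir / "genesets.gmt",
        "truth": outdir / "truth.json",
    }
    gwas.to_csv(paths["sumstats"], sep="\t", index=False, float_format="%.17g")
    genes.to_csv(paths["genes"], sep="\t", index=False)
    ann.to_csv(paths["annotations"], sep="\t", index=False)
    panel.save(paths["panel"])
    eqtl.to_csv(paths["eqtl"], sep="\t", index=False, float_format="%.17g")
    scores.to_csv(paths["scores"], sep="\t", index=False)
    with open(paths["genesets"], "w") as fh:
        causal_genes = truth.causal_genes()
        all_genes = genes["gene_id"].tolist()
        fh.write("causal_set\tsimulated causal genes\t"
                 + "\t".join(causal_genes) + "\n")
        fh.write("random_set\tan arbitrary set\t"
                 + "\t".join(all_genes[::3]) + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth.manifest(), fh, indent=1, sort_keys=True)
    return paths, truth
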