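"""The synthetic-data generator: LD structure, effect injection, determinism."""

import hashlib
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal, norm

from polygene import io
from polygene.simulate import (
    EffectScenario,
    SimulationConfig,
    fixture_config,
    make_fixture_suite,
    null_zscore_genes,
    simulate_gwas,
    simulate_panel,
)


def expected_dosage_corr(latent_rho, f1, f2):
    """Closed-form dosage correlation of the threshold model.

    Haplotype alleles are indicators of correlated latent normals, so their
    correlation is the standardized bivariate orthant probability; summing
    two independent haplotypes leaves the correlation unchanged.
    """
    t1, t2 = norm.ppf(f1), norm.ppf(f2)
    p11 = multivariate_normal.cdf([t1, t2], mean=[0, 0],
                                  cov=[[1, latent_rho], [latent_rho, 1]])
    return (p11 - f1 * f2) / np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))


def small_cfg(**kw):
    base = dict(
        n_individuals=2000, n_genes=6, snps_per_gene=(5, 8),
        effect_scenarios=[], n_intergenic_per_gap=1,
        n_qc_fail_maf=2, n_qc_fail_info=2,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestPanelLd:
    def test_zero_rho_gives_near_independent_snps(self):
        cfg = small_cfg(n_individuals=10_000, ld_block_rho=0.0)
        panel, genes, ann, truth = simulate_panel(cfg, 1)
        gene_snps = truth.layout.snps.loc[
            truth.layout.snps["gene_id"] == "GENE001", "snp_id"].tolist()
        ld = io.compute_ld(panel, gene_snps)
        off = ld.r[~np.eye(len(gene_snps), dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_high_rho_matches_threshold_model_expectation(self):
        cfg = small_cfg(n_individuals=10_000, ld_block_rho=0.9,
                        ld_structure="exchangeable")
        panel, genes, ann, truth = simulate_panel(cfg, 2)
        layout = truth.layout.snps
        sub = layout.loc[layout["gene_id"] == "GENE001"]
        ids, freqs = sub["snp_id"].tolist(), sub["freq"].to_numpy()
        ld = io.compute_ld(panel, ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                expect = expected_dosage_corr(0.9, freqs[i], freqs[j])
                assert ld.r[i, j] == pytest.approx(expect, abs=0.05)

    def test_same_seed_identical_output(self):
        cfg = small_cfg()
        p1, g1, a1, t1 = simulate_panel(cfg, 5)
        p2, g2, a2, t2 = simulate_panel(cfg, 5)
        assert np.array_equal(p1.dosages, p2.dosages)
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(a1, a2)


class TestGwas:
    def test_null_genome_pvalues_uniform(self):
        # no causal SNPs, independent SNPs: per-SNP p-values are uniform
        cfg = SimulationConfig(
            n_individuals=1000, n_genes=500, snps_per_gene=(12, 15),
            ld_block_rho=0.0, effect_scenarios=[], n_intergenic_per_gap=8,
            n_qc_fail_maf=0, n_qc_fail_info=0,
        )
        panel, genes, ann, truth = simulate_panel(cfg, 3)
        gwas = simulate_gwas(panel, truth, cfg, 4)
        assert len(gwas) >= 10_000
        ks = stats.kstest(gwas["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_single_causal_noncentrality(self):
        # E[z^2] = 1 + n h2; average over replicates within 3 SD
        n, h2, reps = 50_000, 0.001, 30
        cfg = SimulationConfig(
            n_individuals=n, n_genes=1, snps_per_gene=(3, 3),
            effect_scenarios=[
                EffectScenario("causal_regulatory", 1, h2_per_snp=h2,
                               n_causal_snps=1)],
            n_intergenic_per_gap=0, n_qc_fail_maf=0, n_qc_fail_info=0,
        )
        z2 = []
        for i in range(reps):
            panel, genes, ann, truth = simulate_panel(cfg, 100 + i)
            gwas = simulate_gwas(panel, truth, cfg, 200 + i)
            snp = list(truth.causal_snps.values())[0][0]
            row = gwas.loc[gwas["snp_id"] == snp].iloc[0]
            z2.append((row["beta"] / row["se"]) ** 2)
        ncp = n * h2
        sd = np.sqrt(2 * (1 + 2 * ncp))
        assert np.mean(z2) == pytest.approx(1 + ncp, abs=3 * sd / np.sqrt(reps))

    def test_beta_se_p_mutually_consistent(self):
        cfg = small_cfg()
        panel, genes, ann, truth = simulate_panel(cfg, 6)
        gwas = simulate_gwas(panel, truth, cfg, 7)
        z = gwas["beta"] / gwas["se"]
        expect = 2 * stats.norm.sf(np.abs(z))
        assert np.allclose(gwas["pvalue"], expect, rtol=1e-6)

    def test_qc_fail_records_violate_thresholds(self):
        cfg = small_cfg()
        panel, genes, ann, truth = simulate_panel(cfg, 8)
        gwas = simulate_gwas(panel, truth, cfg, 9)
        sub = gwas.set_index("snp_id").loc[truth.qc_fail_snps]
        assert ((sub["maf"] < 0.001) | (sub["info"] < 0.8)).all()
        kept = io.apply_qc_filters(gwas)
        assert not set(truth.qc_fail_snps) & set(kept["snp_id"])


class TestShadowGeometry:
    def test_shadow_gene_tags_external_hit(self):
        cfg = fixture_config()
        panel, genes, ann, truth = simulate_panel(cfg, 10)
        gene_info = genes.set_index("gene_id")
        for gid, hit in truth.external_hits.items():
            snps = truth.layout.snps
            gene_snps = snps.loc[snps["gene_id"] == gid, "snp_id"].tolist()
            ld = io.compute_ld(panel, gene_snps + [hit])
            r2s = [ld.r2(s, hit) for s in gene_snps]
            assert min(r2s) >= 0.7  # design target ~0.82 less sampling noise
            # the hit lies outside the gene body but within 200 kb
            hit_pos = int(snps.loc[snps["snp_id"] == hit, "pos"].iloc[0])
            tx_end = int(gene_info.loc[gid, "tx_end"])
            assert tx_end < hit_pos <= tx_end + 200_000

    def test_shadow_genes_have_no_causal_snps(self):
        cfg = fixture_config()
        _, _, _, truth = simulate_panel(cfg, 10)
        for gid in truth.shadow_genes():
            assert gid not in truth.causal_snps


class TestNullZscoreGenes:
    def test_marginals_standard_normal(self, rng):
        zs = np.concatenate([
            z for z, maf, r in null_zscore_genes(300, 6, 0.5, "ar1", rng)])
        assert stats.kstest(zs, "norm").pvalue > 0.001

    def test_correlation_matches_request(self, rng):
        zmat = np.array([
            z for z, maf, r in null_zscore_genes(4000, 2, 0.6, "exchangeable",
                                                 rng)])
        emp = np.corrcoef(zmat, rowvar=False)[0, 1]
        assert emp == pytest.approx(0.6, abs=0.05)


class TestFixtureSuite:
    def test_loads_cleanly_and_manifest_complete(self, fixture_suite):
        paths, truth = fixture_suite
        ss = io.read_summary_stats(paths["sumstats"])
        assert ss.attrs["n_dropped"] == 0
        manifest = json.loads(paths["truth"].read_text())
        kinds = list(manifest["gene_kinds"].values())
        assert kinds.count("shadow_ld") >= 1
        assert kinds.count("causal_coding") >= 1

    def test_regeneration_is_byte_identical(self, fixture_suite, tmp_path):
        paths, truth = fixture_suite
        paths2, _ = make_fixture_suite(7, tmp_path / "again", fixture_config())
        for key in ("sumstats", "genes", "annotations", "panel", "eqtl",
                    "scores", "genesets", "truth"):
            h1 = hashlib.sha256(paths[key].read_bytes()).hexdigest()
            h2 = hashlib.sha256(paths2[key].read_bytes()).hexdigest()
            assert h1 == h2, key
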