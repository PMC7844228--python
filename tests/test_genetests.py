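"""Gene-level statistics: SKAT-O, PCA, ACAT-V and their combination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from polygene.genetests import (
    DEFAULT_RHO_GRID,
    WeightScheme,
    ZVector,
    acat_v,
    cauchy_combine,
    pca_test,
    regularize_ld,
    run_gene,
    skat_o,
    zscores,
)
from polygene.quadform import quadform_pvalue

# Frozen with 30-digit arithmetic (sympy) from the stated formulas.
ACAT_EQUAL_001_02_06 = 0.0289697088944199535824517533913
ACATV_5SNP = 0.0227685007411303296703967050839


def exch(m, rho):
    r = np.full((m, m), rho)
    np.fill_diagonal(r, 1.0)
    return r


class TestZScores:
    def test_scalar_arithmetic_and_vectorization(self):
        df = pd.DataFrame({
            "snp_id": ["a", "b", "c"],
            "beta": [0.02, 0.0, -0.05],
            "se": [0.01, 0.02, 0.025],
            "maf": [0.1, 0.2, 0.3],
        })
        zv = zscores(df)
        assert zv.z == pytest.approx([2.0, 0.0, -2.0])
        # vector result matches elementwise scalar computation
        for i in range(3):
            assert zv.z[i] == df["beta"][i] / df["se"][i]

    def test_nonpositive_se_rejected(self):
        df = pd.DataFrame({"snp_id": ["a"], "beta": [1.0], "se": [0.0],
                           "maf": [0.1]})
        with pytest.raises(ValueError):
            zscores(df)


class TestCauchyCombine:
    def test_single_p_identity(self):
        assert cauchy_combine([0.0731]) == pytest.approx(0.0731, abs=1e-12)

    def test_half_half_is_half(self):
        assert cauchy_combine([0.5, 0.5]) == pytest.approx(0.5, abs=1e-14)

    def test_frozen_high_precision_value(self):
        assert cauchy_combine([0.01, 0.2, 0.6]) == pytest.approx(
            ACAT_EQUAL_001_02_06, abs=1e-12)

    def test_tiny_p_asymptote_continuous(self):
        above = cauchy_combine([2e-15, 0.3])
        below = cauchy_combine([5e-16, 0.3])
        assert 0 < below < above < 1
        # single tiny p passes through almost unchanged
        assert cauchy_combine([1e-20]) == pytest.approx(1e-20, rel=1e-6)

    def test_p_equal_one_truncated(self):
        assert 0 < cauchy_combine([1.0, 1.0]) <= 1.0

    @given(st.lists(st.floats(1e-6, 1 - 1e-6), min_size=2, max_size=8),
           st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_permutation_and_weight_scale_invariance(self, ps, scale):
        w = np.arange(1.0, len(ps) + 1.0)
        p1 = cauchy_combine(ps, w)
        p2 = cauchy_combine(ps[::-1], w[::-1])
        p3 = cauchy_combine(ps, w * scale)
        assert p1 == pytest.approx(p2, rel=1e-9)
        assert p1 == pytest.approx(p3, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cauchy_combine([])


class TestAcatV:
    def test_single_snp_returns_per_snp_p(self):
        z = 1.7
        zv = ZVector(["a"], [z], [0.2])
        assert acat_v(zv) == pytest.approx(2 * stats.norm.sf(z), rel=1e-10)

    def test_all_half_is_half(self):
        z_half = stats.norm.isf(0.25)  # two-sided p = 0.5
        zv = ZVector(list("abcd"), [z_half] * 4, [0.1, 0.2, 0.3, 0.4])
        assert acat_v(zv) == pytest.approx(0.5, abs=1e-9)

    def test_frozen_weighted_example(self):
        # per-SNP two-sided p = (0.02, 0.4, 0.15, 0.8, 0.05)
        ps = np.array([0.02, 0.4, 0.15, 0.8, 0.05])
        z = stats.norm.isf(ps / 2)
        maf = np.array([0.05, 0.1, 0.2, 0.3, 0.45])
        zv = ZVector([f"s{i}" for i in range(5)], z, maf)
        assert acat_v(zv) == pytest.approx(ACATV_5SNP, rel=1e-9)


class TestPcaTest:
    def test_identity_ld_full_variance_is_chi2_m(self):
        z = np.array([1.0, -2.0, 0.5, 1.5])
        zv = ZVector(list("abcd"), z, np.full(4, 0.3))
        p, k = pca_test(zv, np.eye(4), var_fraction=1.0)
        assert k == 4
        assert p == pytest.approx(stats.chi2.sf(np.sum(z ** 2), 4), rel=1e-10)

    def test_perfect_ld_collapses_to_one_component(self):
        m = 4
        z = np.full(m, 2.0)
        zv = ZVector(list("abcd"), z, np.full(m, 0.3))
        p, k = pca_test(zv, exch(m, 1.0) - 1e-12 * 0, var_fraction=0.85)
        assert k == 1
        # projection on the equal-loading component: (sum z / sqrt(m))^2 / m
        t = (z.sum() / np.sqrt(m)) ** 2 / m
        assert p == pytest.approx(stats.chi2.sf(t, 1), rel=1e-8)

    def test_random_case_matches_direct_projection(self, rng):
        m = 5
        a = rng.standard_normal((m, m))
        r = regularize_ld(np.corrcoef(a @ a.T))
        z = rng.standard_normal(m)
        zv = ZVector([f"s{i}" for i in range(m)], z, rng.uniform(0.05, 0.5, m))
        p, k = pca_test(zv, r, var_fraction=0.85)
        # independent recomputation of the projection statistic
        ev, vec = np.linalg.eigh(r)
        idx = np.argsort(-ev)
        ev, vec = ev[idx], vec[:, idx]
        kk = int(np.argmax(np.cumsum(ev) / ev.sum() >= 0.85 - 1e-12)) + 1
        t = sum((vec[:, i] @ z) ** 2 / ev[i] for i in range(kk))
        assert k == kk
        assert p == pytest.approx(stats.chi2.sf(t, kk), rel=1e-9)

    def test_monotone_in_signal_for_fixed_k(self, rng):
        z = rng.standard_normal(6)
        zv1 = ZVector([f"s{i}" for i in range(6)], z, np.full(6, 0.2))
        zv2 = ZVector([f"s{i}" for i in range(6)], 2.5 * z, np.full(6, 0.2))
        p1, _ = pca_test(zv1, np.eye(6), var_fraction=1.0)
        p2, _ = pca_test(zv2, np.eye(6), var_fraction=1.0)
        assert p2 <= p1


class TestSkatO:
    def test_single_snp_degeneracy(self):
        zv = ZVector(["a"], [1.959964], [0.3])
        for grid in (None, [0.0], [1.0], [0.0, 0.5, 1.0]):
            p, _ = skat_o(zv, np.eye(1), rho_grid=grid)
            assert p == pytest.approx(0.05, abs=1e-6)

    def test_burden_closed_form(self):
        z = np.ones(4)
        zv = ZVector(list("abcd"), z, np.full(4, 0.3))
        r = exch(4, 0.3)
        w = WeightScheme(mode="equal")
        p, rho = skat_o(zv, r, w, rho_grid=[1.0])
        expect = stats.chi2.sf(z.sum() ** 2 / r.sum(), 1)
        assert rho == 1.0
        assert p == pytest.approx(expect, rel=1e-8)

    def test_rho_zero_equals_pure_skat_quadform(self, rng):
        m = 5
        r = exch(m, 0.4)
        z = rng.standard_normal(m)
        zv = ZVector([f"s{i}" for i in range(m)], z, np.full(m, 0.25))
        p, _ = skat_o(zv, r, WeightScheme(mode="equal"), rho_grid=[0.0])
        lam = np.clip(np.linalg.eigvalsh(r), 0, None)
        assert p == pytest.approx(quadform_pvalue(lam, z @ z), rel=1e-6)

    def test_omnibus_matches_minp_monte_carlo(self, rng):
        # 4 SNPs, exchangeable LD r = 0.3, fixed z: the SKAT-O p-value is
        # P(min_rho p_rho < T_obs) under z ~ N(0, R); estimated by
        # simulation through the per-rho thresholds
        from polygene.genetests import _quantile

        m = 4
        r = exch(m, 0.3)
        z = np.array([1.2, -0.4, 2.1, 0.3])
        zv = ZVector(list("abcd"), z, np.array([0.1, 0.2, 0.3, 0.4]))
        w = WeightScheme(mode="equal")
        p_skato, _ = skat_o(zv, r, w)

        grid = DEFAULT_RHO_GRID
        q0, qb = float(z @ z), float(z.sum() ** 2)
        ev, vec = np.linalg.eigh(r)
        s_half = (vec * np.sqrt(np.clip(ev, 0, None))) @ vec.T
        lam_rho, p_rho = [], []
        for rho in grid:
            if rho == 1.0:
                s = float(r.sum())
                lam_rho.append(np.array([s]))
                p_rho.append(stats.chi2.sf(qb / s, 1))
            else:
                a = s_half @ ((1 - rho) * np.eye(m) + rho) @ s_half
                lam = np.clip(np.linalg.eigvalsh(a), 0, None)
                lam_rho.append(lam)
                p_rho.append(quadform_pvalue(lam, (1 - rho) * q0 + rho * qb))
        t_min = min(p_rho)
        thr = np.array([
            (1 - rho) * q0 + rho * qb if p <= t_min * (1 + 1e-12)
            else (float(r.sum()) * stats.chi2.isf(t_min, 1) if rho == 1.0
                  else _quantile(lam, t_min))
            for rho, lam, p in zip(grid, lam_rho, p_rho)
        ])
        n = 2 * 10 ** 5
        chol = np.linalg.cholesky(r)
        zz = rng.standard_normal((n, m)) @ chol.T
        qq0 = (zz ** 2).sum(axis=1)
        qqb = zz.sum(axis=1) ** 2
        qr = (1 - grid[None, :]) * qq0[:, None] + grid[None, :] * qqb[:, None]
        mc = (qr > thr[None, :]).any(axis=1).mean()
        se = np.sqrt(mc * (1 - mc) / n)
        assert p_skato == pytest.approx(mc, abs=3 * se)

    def test_bonferroni_bracket(self, rng):
        # omnibus p always lies between min-p and grid-size * min-p
        for _ in range(5):
            m = int(rng.integers(2, 7))
            r = regularize_ld(exch(m, float(rng.uniform(0, 0.8))))
            z = rng.standard_normal(m) * 1.5
            zv = ZVector([f"s{i}" for i in range(m)], z,
                         rng.uniform(0.05, 0.5, m))
            p, _ = skat_o(zv, r)
            grid = DEFAULT_RHO_GRID
            ps = []
            for rho in grid:
                pr, _ = skat_o(zv, r, rho_grid=[rho])
                ps.append(pr)
            t = min(ps)
            assert t - 1e-9 <= p <= min(1.0, t * len(grid)) + 1e-9


class TestRunGene:
    def test_single_snp_all_methods_agree(self):
        z = 2.3
        zv = ZVector(["a"], [z], [0.2])
        res = run_gene("g", "all", zv, np.eye(1))
        expect = 2 * stats.norm.sf(z)
        for p in (res.p_skato, res.p_pca, res.p_acatv, res.p_acato):
            assert p == pytest.approx(expect, abs=1e-6)

    def test_empty_set_flagged_untested(self):
        res = run_gene("g", "exonic", None, np.eye(1))
        assert not res.tested

    def test_all_pvalues_in_unit_interval(self, rng):
        for _ in range(10):
            m = int(rng.integers(1, 9))
            r = regularize_ld(exch(m, float(rng.uniform(0, 0.9))))
            zv = ZVector([f"s{i}" for i in range(m)],
                         rng.standard_normal(m) * 3,
                         rng.uniform(0.01, 0.5, m))
            res = run_gene("g", "all", zv, r)
            for p in (res.p_skato, res.p_pca, res.p_acatv, res.p_acato):
                assert 0 < p <= 1

    def test_strong_signal_beats_threshold(self, rng):
        z = rng.standard_normal(6) + np.array([8, 7, 0, 0, 6, 0])
        zv = ZVector([f"s{i}" for i in range(6)], z, rng.uniform(0.1, 0.5, 6))
        res = run_gene("g", "all", zv, np.eye(6))
        assert res.p_acato < 2.5e-5


class TestLdRegularization:
    def test_indefinite_matrix_projected_to_psd(self):
        r = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        out = regularize_ld(r)
        ev = np.linalg.eigvalsh(out)
        assert ev.min() >= -1e-10
        assert np.diag(out) == pytest.approx(np.ones(3), abs=1e-12)

    def test_psd_matrix_unchanged(self):
        r = exch(4, 0.3)
        assert np.allclose(regularize_ld(r), r)
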