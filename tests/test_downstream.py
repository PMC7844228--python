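"""Pathogenicity classification and hypergeometric enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polygene.downstream import (
    PredictorScores,
    adjust,
    classify_pathogenic,
    hypergeom_enrich,
    read_gmt,
    select_coding_variants,
)
from polygene.regions import build_scenario_sets


class TestClassifyPathogenic:
    def test_single_flag_suffices(self):
        status, flags = classify_pathogenic(
            PredictorScores("s", sift=0.3, polyphen=0.2, fathmm_xf=0.4,
                            cadd_phred=21.0))
        assert status == "pathogenic"
        assert flags == {"sift": False, "polyphen": False, "fathmm_xf": False,
                         "cadd_phred": True}

    def test_all_exact_boundaries_fail(self):
        status, flags = classify_pathogenic(
            PredictorScores("s", sift=0.05, polyphen=0.5, fathmm_xf=0.5,
                            cadd_phred=20.0))
        assert status == "not_flagged"
        assert not any(flags.values())

    def test_all_four_flags(self):
        status, flags = classify_pathogenic(
            PredictorScores("s", sift=0.01, polyphen=0.9, fathmm_xf=0.9,
                            cadd_phred=30.0))
        assert status == "pathogenic"
        assert all(flags.values())

    @pytest.mark.parametrize("kw,flag", [
        ({"sift": 0.049}, "sift"),
        ({"polyphen": 0.51}, "polyphen"),
        ({"fathmm_xf": 0.51}, "fathmm_xf"),
        ({"cadd_phred": 20.01}, "cadd_phred"),
    ])
    def test_each_threshold_individually(self, kw, flag):
        status, flags = classify_pathogenic(PredictorScores("s", **kw))
        assert status == "pathogenic"
        assert flags[flag] and sum(flags.values()) == 1

    def test_missing_scores_never_flag(self):
        status, _ = classify_pathogenic(PredictorScores("s", sift=0.5))
        assert status == "not_flagged"

    def test_all_missing_is_undetermined(self):
        status, _ = classify_pathogenic(PredictorScores("s"))
        assert status == "undetermined"

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
           st.floats(0, 60))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_severity(self, sift, poly, fathmm, cadd):
        base = classify_pathogenic(
            PredictorScores("s", sift=sift, polyphen=poly, fathmm_xf=fathmm,
                            cadd_phred=cadd))[0]
        worse = classify_pathogenic(
            PredictorScores("s", sift=sift * 0.5, polyphen=poly + (1 - poly) / 2,
                            fathmm_xf=fathmm + (1 - fathmm) / 2,
                            cadd_phred=cadd + 10))[0]
        if base == "pathogenic":
            assert worse == "pathogenic"


class TestSelectCodingVariants:
    def make_inputs(self):
        ann = pd.DataFrame({
            "snp_id": ["c1", "c2", "i1", "c3"],
            "functional_class": ["nonsynonymous", "exonic_other", "intron",
                                 "nonsynonymous"],
        })
        records = pd.DataFrame({
            "snp_id": ["c1", "c2", "i1", "c3"],
            "pvalue": [0.01, 0.06, 0.001, 0.04],
        })
        sets = {"g1": build_scenario_sets("g1", ["c1", "c2", "i1", "c3"], ann)}
        return ann, records, sets

    def test_rules(self):
        ann, rec, sets = self.make_inputs()
        got = select_coding_variants(["g1"], sets, rec, ann, 0.05)
        # c2 fails p<0.05; i1 is intronic
        assert got == ["c1", "c3"]

    def test_matches_brute_force(self, rng):
        ann, rec, sets = self.make_inputs()
        got = set(select_coding_variants(["g1"], sets, rec, ann, 0.05))
        classes = dict(zip(ann["snp_id"], ann["functional_class"]))
        ps = dict(zip(rec["snp_id"], rec["pvalue"]))
        brute = {s for s in ["c1", "c2", "i1", "c3"]
                 if classes[s] in ("nonsynonymous", "exonic_other")
                 and ps[s] < 0.05}
        assert got == brute


class TestHypergeomEnrich:
    def test_zero_overlap_is_one(self):
        res = hypergeom_enrich(["a", "b"], ["c", "d"],
                               ["a", "b", "c", "d", "e"])
        assert res.p == 1.0

    def test_complete_overlap_exact_combinatorics(self):
        universe = [f"g{i}" for i in range(20)]
        gene_set = universe[:5]
        res = hypergeom_enrich(gene_set, gene_set, universe)
        assert res.p == pytest.approx(1.0 / math.comb(20, 5), rel=1e-12)

    def test_matches_brute_force_summation(self, rng):
        for _ in range(20):
            n_univ = int(rng.integers(10, 60))
            universe = [f"g{i}" for i in range(n_univ)]
            gene_set = list(rng.choice(universe, size=rng.integers(1, n_univ),
                                       replace=False))
            glist = list(rng.choice(universe, size=rng.integers(1, n_univ),
                                    replace=False))
            res = hypergeom_enrich(glist, gene_set, universe)
            K, n = len(gene_set), len(glist)
            brute = sum(
                math.comb(K, k) * math.comb(n_univ - K, n - k)
                for k in range(res.overlap, min(K, n) + 1)
                if n - k <= n_univ - K
            ) / math.comb(n_univ, n)
            assert res.p == pytest.approx(brute, abs=1e-12)

    def test_set_restricted_to_universe(self):
        res = hypergeom_enrich(["a"], ["a", "zzz"], ["a", "b", "c"])
        assert res.set_size == 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich([], [], [])

    def test_list_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(["x"], ["a"], ["a", "b"])


def bh_brute_force(p):
    """Independent step-up implementation of Benjamini-Hochberg q-values."""
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestAdjust:
    def test_single_p_unchanged(self):
        for method in ("bh", "bonferroni"):
            assert adjust([0.031], method)[0] == pytest.approx(0.031)

    def test_bh_hand_example(self):
        q = adjust([0.01, 0.02, 0.03, 0.5], "bh")
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5], atol=1e-12)

    def test_bh_matches_brute_force(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 40)))
            assert np.allclose(adjust(p, "bh"), bh_brute_force(p), atol=1e-12)

    def test_bonferroni_scaling(self, rng):
        p = rng.uniform(0, 1, size=7)
        assert np.allclose(adjust(p, "bonferroni"), np.minimum(p * 7, 1.0),
                           atol=1e-15)

    def test_bonferroni_dominates_bh(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 30)))
            assert np.all(adjust(p, "bonferroni") >= adjust(p, "bh") - 1e-12)

    def test_bh_controls_fdr_on_uniform_null(self, rng):
        # all-null p-values: any rejection is a false discovery, so the
        # FDR equals the probability of rejecting at all, bounded by 0.05
        reps, m = 2000, 20
        fdp = np.empty(reps)
        for i in range(reps):
            q = adjust(rng.uniform(size=m), "bh")
            fdp[i] = 1.0 if (q <= 0.05).any() else 0.0
        se = fdp.std(ddof=1) / np.sqrt(reps)
        assert fdp.mean() <= 0.05 + 3 * se


class TestGmt:
    def test_roundtrip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("setA\tdesc\tg1\tg2\ng3\nsetB\tdesc\tg9\n")
        sets = read_gmt(p)
        assert sets["setA"] == ["g1", "g2"]
        assert sets["setB"] == ["g9"]
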