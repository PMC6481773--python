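"""Nominal-gene overrepresentation, score regression, overlap test, ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ewdense as e
from ewdense.containers import GwasGeneStats
from ewdense.megamodules import MegaModule
from ewdense.validation import NominalGeneSet


def _gwas(pmap, study="val"):
    return GwasGeneStats(study, pd.Series(pmap))


class TestNominalGenes:
    def test_no_gene_below_threshold(self):
        gwas = _gwas({f"G{i}": 0.5 for i in range(10)})
        assert e.nominal_genes(gwas).genes == frozenset()

    def test_boundary_is_strict(self):
        gwas = _gwas({"A": 0.001, "B": 0.0009})
        assert e.nominal_genes(gwas).genes == frozenset({"B"})

    def test_recovers_planted_signal(self):
        pmap = {f"G{i:03d}": 0.5 for i in range(100)}
        planted = [f"P{i:02d}" for i in range(20)]
        pmap.update({g: 1e-5 for g in planted})
        assert e.nominal_genes(_gwas(pmap)).genes == frozenset(planted)

    def test_restriction_to_background(self):
        gwas = _gwas({"A": 1e-5, "B": 1e-5})
        assert e.nominal_genes(gwas, restrict_to={"A"}).genes == frozenset({"A"})


class TestOverrepTest:
    def test_matches_hypergeometric_tail(self):
        background = [f"G{i:04d}" for i in range(1000)]
        nominal = NominalGeneSet("v", 0.001, frozenset(background[:20]))
        module = set(background[:10])  # all 10 nominal
        b = 20000
        p_emp = e.overrep_test(module, nominal, background, b=b, seed=0)
        p_exact = stats.hypergeom.sf(9, 1000, 20, 10)
        se = np.sqrt(max(p_exact * (1 - p_exact), p_exact) / b)
        assert abs(p_emp - p_exact) < 3 * se + 1 / (b + 1)

    def test_saturated_null_gives_one(self):
        background = [f"G{i}" for i in range(50)]
        nominal = NominalGeneSet("v", 0.001, frozenset(background))
        assert e.overrep_test(background[:10], nominal, background,
                              b=500, seed=1) == 1.0

    def test_floor_when_observed_beats_all_draws(self):
        background = [f"G{i:03d}" for i in range(500)]
        nominal = NominalGeneSet("v", 0.001, frozenset(background[:5]))
        module = set(background[:5])  # all nominal genes captured
        p = e.overrep_test(module, nominal, background, b=999, seed=2)
        assert p == pytest.approx(1 / 1000)

    def test_module_larger_than_background_errors(self):
        nominal = NominalGeneSet("v", 0.001, frozenset())
        with pytest.raises(ValueError):
            e.overrep_test({"A", "B"}, nominal, ["A"], b=100)


class TestOverrepMegamodules:
    def _mm(self, name, genes):
        return MegaModule(name=name, constituents=(0,),
                          genes=frozenset(genes), edges=frozenset())

    def test_single_nominal_gene_skipped_and_threshold(self):
        background = [f"G{i:03d}" for i in range(200)]
        nominal = NominalGeneSet("v", 0.001, frozenset(background[:10]))
        mms = [
            self._mm("one", background[:1] + background[50:58]),   # 1 hit
            self._mm("two", background[:6] + background[60:64]),   # 6 hits
            self._mm("three", background[6:9] + background[70:77]),  # 3 hits
        ]
        df = e.overrep_megamodules(mms, nominal, background, b=2000, seed=0)
        assert set(df["megamodule"]) == {"two", "three"}
        assert np.allclose(df["threshold"], 0.05 / 2)
        assert df.loc[df["megamodule"] == "two", "significant"].item()


class TestScoreRegression:
    def _mms(self, sns, means):
        out = []
        for i, (sn, mu) in enumerate(zip(sns, means)):
            genes = frozenset({f"M{i}A", f"M{i}B"})
            out.append(MegaModule(name=f"mm{i}", constituents=(i,),
                                  genes=genes, edges=frozenset(), s_n=sn))
        return out

    def test_noiseless_line_recovers_slope(self):
        sns = np.linspace(1.0, 10.0, 10)
        means = 0.5 - 0.02 * sns
        mms = self._mms(sns, means)
        pmap = {}
        for mm, mu in zip(mms, means):
            for g in mm.genes:
                pmap[g] = float(mu)
        beta, p = e.score_regression(mms, _gwas(pmap))
        assert beta == pytest.approx(-0.02, abs=1e-10)
        assert p < 1e-12

    def test_permuted_scores_give_uniform_p(self):
        rng = np.random.default_rng(1)
        pvals = []
        base_means = rng.uniform(0.2, 0.8, size=12)
        for _ in range(200):
            sns = rng.permutation(np.linspace(1, 5, 12))
            mms = self._mms(sns, base_means)
            pmap = {g: float(mu) for mm, mu in zip(mms, base_means)
                    for g in mm.genes}
            _, p = e.score_regression(mms, _gwas(pmap))
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_shared_planted_signal_gives_negative_slope(self):
        """When the validation study shares half the planted module,
        higher-scoring mega-modules carry lower mean validation p."""
        neg = 0
        for i in range(5):
            cfg = e.SyntheticConfig(n_genes=300, planted_size=20, seed=700 + i)
            ppi, truth = e.generate_ppi(cfg)
            gwas = e.generate_gwas(truth, cfg.gwas_alpha, cfg.seed)
            rng = np.random.default_rng(800 + i)
            planted = sorted(truth.planted_genes)
            val_signal = frozenset(rng.choice(planted, size=10,
                                              replace=False))
            gval = e.generate_gwas(truth, cfg.gwas_alpha, cfg.seed + 1,
                                   study="val", signal_genes=val_signal)
            ctrl, trt = e.generate_expression(truth)
            bg = e.build_background(ppi, gwas.genes, set(ctrl.values.index))
            wn = e.WeightedNetwork.build(bg, gwas, ctrl, trt)
            modules = e.search_all(wn)
            _, sig = e.module_significance(modules, wn, b=300, seed=i)
            mms = e.score_megamodules(e.merge_modules(sig, wn), wn,
                                      b=300, seed=i)
            sig_mms = [mm for mm in mms if mm.q < 0.05]
            beta, _ = e.score_regression(sig_mms, gval)
            neg += beta < 0
        assert neg >= 4

    def test_too_few_points_error(self):
        mms = self._mms([1.0, 2.0], [0.5, 0.4])
        pmap = {g: 0.5 for mm in mms for g in mm.genes}
        with pytest.raises(ValueError):
            e.score_regression(mms, _gwas(pmap))


class TestOverlapTest:
    def test_printed_megamodule_overlap_is_extreme(self):
        p = e.overlap_test(392, 195, 6050, overlap=72)
        assert p <= 2.2e-16

    def test_disjoint_sets_give_one(self):
        assert e.overlap_test({"A"}, {"B"}, 100) == 1.0

    def test_subset_matches_exact_summation_oracle(self):
        n_bg, na, nb = 60, 8, 20
        a = {f"G{i}" for i in range(na)}
        b = {f"G{i}" for i in range(nb)}  # a subset of b, overlap = 8
        p = e.overlap_test(a, b, n_bg)
        total = 0.0
        from math import comb
        for x in range(na, na + 1):  # P(X >= 8) with max(X)=8
            total += comb(nb, x) * comb(n_bg - nb, na - x) / comb(n_bg, na)
        assert p == pytest.approx(total, rel=1e-10)

    def test_monotone_in_overlap(self):
        ps = [e.overlap_test(50, 40, 1000, overlap=o) for o in range(0, 20)]
        assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps, ps[1:]))

    def test_oversized_set_errors(self):
        with pytest.raises(ValueError):
            e.overlap_test(200, 10, 100, overlap=5)


class TestOra:
    def test_exact_tail_and_expected_hit_filtering(self):
        universe = [f"G{i:05d}" for i in range(10000)]
        # 5 of the 100 query genes fall in the 500-gene set: expected ~5 hits
        query = set(universe[:5]) | set(universe[9000:9095])
        sets = {"S": set(universe[:500])}
        df = e.ora_enrichment(query, sets, universe)
        assert df.empty  # p ~ 0.56 is filtered out by p < 0.01
        p = stats.hypergeom.sf(4, 10000, 500, 100)
        assert p == pytest.approx(0.56, abs=0.05)

    def test_min_hit_filter(self):
        universe = [f"G{i}" for i in range(1000)]
        sets = {"S": set(universe[:2])}
        df = e.ora_enrichment(set(universe[:2]), sets, universe)
        assert df.empty  # 2 hits < 3 despite tiny p

    def test_set_size_boundary(self):
        universe = [f"G{i:05d}" for i in range(5000)]
        big = {"B": set(universe[:1001])}
        small = {"S": set(universe[:1000])}
        query = set(universe[:50])
        assert e.ora_enrichment(query, big, universe).empty
        kept = e.ora_enrichment(query, small, universe)
        assert list(kept["set_name"]) == ["S"]

    def test_bonferroni_within_category(self):
        universe = [f"G{i:04d}" for i in range(2000)]
        query = set(universe[:30])
        sets = {f"S{j}": set(universe[:40]) | {universe[100 + j]}
                for j in range(4)}
        cats = {name: "GO" for name in sets}
        df = e.ora_enrichment(query, sets, universe, categories=cats)
        assert np.allclose(df["q_bonferroni"],
                           np.minimum(1.0, df["p"] * 4))

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            e.ora_enrichment({"A"}, {"S": {"A"}}, [])
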