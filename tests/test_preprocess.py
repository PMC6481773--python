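"""Responsive calls, probeset collapse, homolog mapping, background build."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ewdense as e
from ewdense.containers import SScorePanel
from ewdense.preprocess import bh_qvalues


def _chi2_sf_even_df(x, df):
    """Closed-form chi-square survival function for even df (oracle)."""
    k = df // 2
    half = x / 2.0
    term, total = 1.0, 1.0
    for i in range(1, k):
        term *= half / i
        total += term
    return math.exp(-half) * total


class TestFisherCombine:
    def test_all_ones_gives_zero(self):
        stat, p = e.fisher_combine([1.0, 1.0])
        assert stat == 0.0 and p == 1.0

    def test_two_tenths(self):
        stat, p = e.fisher_combine([0.1, 0.1])
        assert stat == pytest.approx(9.21034, abs=1e-4)
        assert p == pytest.approx(0.05605, abs=2e-4)

    def test_single_p_is_identity(self):
        stat, p = e.fisher_combine([0.05])
        assert stat == pytest.approx(-2 * math.log(0.05), rel=1e-12)
        assert p == pytest.approx(0.05, rel=1e-12)

    @pytest.mark.parametrize("pvals", [
        [0.5], [0.01, 0.2], [0.9, 0.4, 0.3, 0.001], [1.0, 0.25, 0.6],
    ])
    def test_matches_even_df_closed_form(self, pvals):
        stat, p = e.fisher_combine(pvals)
        assert p == pytest.approx(_chi2_sf_even_df(stat, 2 * len(pvals)),
                                  abs=1e-12)

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            e.fisher_combine([])
        with pytest.raises(ValueError):
            e.fisher_combine([0.0, 0.5])


def _panel(values, region="synthetic"):
    arr = np.asarray(values, dtype=float)
    return SScorePanel(region, pd.DataFrame(
        arr,
        index=[f"PS{i:03d}" for i in range(arr.shape[0])],
        columns=[f"BXD{j:03d}" for j in range(arr.shape[1])],
    ))


class TestResponsiveCalls:
    def test_all_zero_scores_give_p_one(self):
        calls = e.responsive_calls(_panel(np.zeros((5, 10))), n_perm=200,
                                   seed=0)
        assert (calls.table["p_empirical"] == 1.0).all()
        assert (calls.table["statistic"] == 0.0).all()

    def test_extreme_probeset_hits_permutation_floor(self):
        values = np.random.default_rng(0).normal(size=(50, 30))
        values[0] = 5.0
        calls = e.responsive_calls(_panel(values), n_perm=200, seed=1)
        row = calls.table[calls.table["probeset"] == "PS000"].iloc[0]
        assert row["p_empirical"] == pytest.approx(1 / 201)

    def test_null_panel_empirical_p_uniform(self):
        values = np.random.default_rng(42).normal(size=(2000, 12))
        calls = e.responsive_calls(_panel(values), n_perm=500, seed=2)
        ks = stats.kstest(calls.table["p_empirical"], "uniform").statistic
        assert ks < 0.05

    def test_nonfinite_scores_error(self):
        panel = _panel(np.zeros((3, 5)))
        panel.values.iloc[0, 0] = np.inf
        with pytest.raises(ValueError):
            e.responsive_calls(panel, n_perm=100)


class TestFilterResponsive:
    def _calls(self, qmap):
        rows = [{"probeset": ps, "region": rg, "statistic": 1.0, "df": 4,
                 "p_analytic": q, "p_empirical": q, "q": q}
                for ps, per_region in qmap.items()
                for rg, q in per_region.items()]
        from ewdense.preprocess import ResponsiveCalls
        return ResponsiveCalls(pd.DataFrame(rows))

    def test_any_region_rule(self):
        calls = self._calls({"A": {"PFC": 0.05, "NAC": 0.5, "VTA": 0.5}})
        assert e.filter_responsive(calls, 0.1) == {"A"}

    def test_boundary_is_strict(self):
        calls = self._calls({"A": {"PFC": 0.1, "NAC": 0.1, "VTA": 0.1}})
        assert e.filter_responsive(calls, 0.1) == set()

    def test_null_panel_fdr_calibration(self):
        rng = np.random.default_rng(3)
        retained = total = 0
        for s in range(10):
            values = rng.normal(size=(400, 10))
            calls = e.responsive_calls(_panel(values), n_perm=200, seed=s)
            retained += len(e.filter_responsive(calls, 0.1))
            total += 400
        assert retained / total <= 0.2  # <= 2x the nominal FDR


class TestCollapse:
    def _inputs(self):
        probes = ["P1A", "P1B", "P2A"]
        strains = ["S1", "S2"]
        ctrl = pd.DataFrame([[7.0, 7.2], [9.2, 9.4], [5.0, 5.2]],
                            index=probes, columns=strains)
        trt = pd.DataFrame([[7.1, 7.1], [9.3, 9.3], [5.1, 5.1]],
                           index=probes, columns=strains)
        pm = pd.Series(["G1", "G1", "G2"], index=pd.Index(probes), name="gene")
        return ctrl, trt, pm

    def test_max_mean_probeset_wins(self):
        ctrl, trt, pm = self._inputs()
        panels, chosen = e.collapse_probesets(
            {"control": ctrl, "treatment": trt}, pm)
        assert chosen["G1"] == "P1B"
        assert panels["control"].values.loc["G1", "S1"] == 9.2

    def test_single_probeset_passthrough(self):
        ctrl, trt, pm = self._inputs()
        panels, chosen = e.collapse_probesets(
            {"control": ctrl, "treatment": trt}, pm)
        assert chosen["G2"] == "P2A"
        assert (panels["treatment"].values.loc["G2"] == [5.1, 5.1]).all()

    def test_tie_breaks_to_smallest_probeset_id(self):
        probes = ["PB", "PA"]
        df = pd.DataFrame([[8.0, 8.0], [8.0, 8.0]], index=probes,
                          columns=["S1", "S2"])
        pm = pd.Series(["G1", "G1"], index=pd.Index(probes))
        _, chosen1 = e.collapse_probesets({"control": df, "treatment": df}, pm)
        _, chosen2 = e.collapse_probesets({"control": df, "treatment": df}, pm)
        assert chosen1["G1"] == "PA" and chosen2["G1"] == "PA"

    def test_multi_gene_probeset_errors(self):
        ctrl, trt, _ = self._inputs()
        pm = pd.Series(["G1", "G2"],
                       index=pd.Index(["P1A", "P1A"]), name="gene")
        with pytest.raises(ValueError):
            e.collapse_probesets({"control": ctrl, "treatment": trt}, pm)


class TestMapHomologs:
    def test_identity_map_is_noop(self):
        expr = pd.DataFrame(np.arange(6.0).reshape(3, 2),
                            index=["A", "B", "C"], columns=["S1", "S2"])
        table = pd.Series(["A", "B", "C"], index=pd.Index(["A", "B", "C"]))
        out = e.map_homologs(expr, table)
        assert list(out.index) == ["A", "B", "C"]

    def test_unmapped_genes_dropped(self):
        expr = pd.DataFrame(np.ones((10, 2)),
                            index=[f"G{i}" for i in range(10)],
                            columns=["S1", "S2"])
        table = pd.Series([f"H{i}" for i in range(8)],
                          index=pd.Index([f"G{i}" for i in range(8)]))
        assert e.map_homologs(expr, table).shape[0] == 8

    def test_collision_keeps_higher_mean_deterministically(self):
        expr = pd.DataFrame([[5.0, 5.0], [9.0, 9.0]], index=["A", "B"],
                            columns=["S1", "S2"])
        table = pd.Series(["T", "T"], index=pd.Index(["A", "B"]))
        for _ in range(3):
            out = e.map_homologs(expr, table)
            assert list(out.index) == ["T"]
            assert out.loc["T", "S1"] == 9.0

    def test_empty_result_errors(self):
        expr = pd.DataFrame([[1.0]], index=["A"], columns=["S1"])
        with pytest.raises(ValueError):
            e.map_homologs(expr, pd.Series(["X"], index=pd.Index(["Y"])))


class TestBackground:
    def test_triangle_reduced_to_edge(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        bg = e.build_background(g, {"A", "B"}, {"A", "B"})
        assert set(bg.edges) == {("A", "B")} or set(bg.edges) == {("B", "A")}

    def test_identity_universes_drop_only_isolates(self):
        g = nx.Graph([("A", "B")])
        g.add_node("C")
        bg = e.build_background(g, g.nodes, g.nodes)
        assert set(bg.nodes) == {"A", "B"}

    def test_counts_match_set_arithmetic_oracle(self, small_bundle):
        b = small_bundle
        gwas_genes = b.gwas_discovery.genes
        expr_genes = set(b.expr_ctrl.values.index)
        bg = e.build_background(b.ppi, gwas_genes, expr_genes)
        keep = set(b.ppi.nodes) & gwas_genes & expr_genes
        expected = {
            n for n in keep
            if any(nb in keep for nb in b.ppi.neighbors(n))
        }
        assert set(bg.nodes) == expected

    def test_empty_intersection_errors(self):
        g = nx.Graph([("A", "B")])
        with pytest.raises(ValueError):
            e.build_background(g, {"X"}, {"Y"})


def test_bh_qvalues_match_step_up_oracle():
    rng = np.random.default_rng(5)
    p = rng.uniform(size=100) ** 2
    q = bh_qvalues(p)
    # reference step-up rule coded independently
    order = np.argsort(p)
    n = len(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ref = np.minimum.accumulate(ranked[::-1])[::-1]
    expected = np.empty(n)
    expected[order] = np.minimum(ref, 1.0)
    assert np.allclose(q, expected, atol=1e-12)
    assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()
    assert (q >= p - 1e-12).all() and (q <= 1).all()
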