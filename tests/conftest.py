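"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

import ewdense as e


# ---------------------------------------------------------------------------
# independent step-by-step greedy oracle
#
# Recomputes everything from scratch at every step — no incremental sums, no
# shared code with the search module beyond the published formulas.

def greedy_oracle(graph: nx.Graph, z: dict, w: dict, seed_gene: str,
                  r: float = 0.005) -> frozenset:
    """Reference greedy growth; returns the final gene set."""
    z_all = [z[g] for g in graph.nodes]
    w_all = [w[tuple(sorted(ed))] for ed in graph.edges]
    mean_z = sum(z_all) / len(z_all)
    mean_w = sum(w_all) / len(w_all)
    var_z = sum((v - mean_z) ** 2 for v in z_all) / len(z_all)
    var_w = sum((v - mean_w) ** 2 for v in w_all) / len(w_all)
    lam = (sum(abs(v) for v in w_all) / len(w_all)) / (
        sum(abs(v) for v in z_all) / len(z_all)
        + sum(abs(v) for v in w_all) / len(w_all)
    )
    denom = math.sqrt(lam**2 * var_z + (1 - lam) ** 2 * var_w)

    def sn(members: set) -> float:
        k = len(members)
        edges = [tuple(sorted((u, v))) for u, v in graph.edges(members)
                 if u in members and v in members]
        edges = sorted(set(edges))
        m = len(edges)
        s = lam * sum(z[g] for g in members) / math.sqrt(k)
        mean = lam * math.sqrt(k) * mean_z
        if m:
            s += (1 - lam) * sum(w[ed] for ed in edges) / math.sqrt(m)
            mean += (1 - lam) * math.sqrt(m) * mean_w
        return (s - mean) / denom

    members = {seed_gene}
    current = sn(members)
    while True:
        frontier = sorted(
            {nb for g in members for nb in graph.neighbors(g)} - members
        )
        if not frontier:
            break
        best = None
        for cand in frontier:
            val = sn(members | {cand})
            key = (val, z[cand])
            # strict > keeps the lexicographically first among exact ties
            if best is None or key > best[0]:
                best = (key, cand)
        (val, _), cand = best[0], best[1]
        if current > 0:
            ok = val >= current * (1 + r)
        else:
            ok = val >= current + abs(current) * r
        if not ok:
            break
        members.add(cand)
        current = val
    return frozenset(members)


def random_weighted_graph(graph: nx.Graph, rng: np.random.Generator):
    """Random node/edge weights on a graph, as plain dicts."""
    z = {g: float(rng.normal()) for g in graph.nodes}
    w = {tuple(sorted((u, v))): float(abs(rng.normal()))
         for u, v in graph.edges}
    return z, w


def small_connected_graphs(max_nodes: int = 6):
    """All connected simple graphs with 3..max_nodes nodes and >= 2 edges."""
    out = []
    for g in nx.graph_atlas_g()[1:]:
        n = g.number_of_nodes()
        if n < 3 or n > max_nodes:
            continue
        if g.number_of_edges() < 2:
            continue
        if not nx.is_connected(g):
            continue
        out.append(nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes}))
    return out


def random_connected_subgraph(adj: dict, k: int, rng: np.random.Generator):
    """Node set of a random connected k-subgraph grown by frontier expansion."""
    nodes = sorted(adj)
    start = nodes[int(rng.integers(len(nodes)))]
    members = {start}
    frontier = set(adj[start])
    while len(members) < k and frontier:
        pick = sorted(frontier)[int(rng.integers(len(frontier)))]
        members.add(pick)
        frontier |= set(adj[pick]) - members
        frontier.discard(pick)
    return members


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def small_bundle():
    """300-gene strong-signal bundle shared across tests."""
    cfg = e.SyntheticConfig(n_genes=300, planted_size=20, seed=7)
    return e.generate_bundle(cfg)


@pytest.fixture(scope="session")
def small_weighted(small_bundle):
    """Weighted network on the full small-bundle graph (no responsive filter)."""
    b = small_bundle
    bg = e.build_background(
        b.ppi, b.gwas_discovery.genes, set(b.expr_ctrl.values.index)
    )
    return e.WeightedNetwork.build(bg, b.gwas_discovery, b.expr_ctrl,
                                   b.expr_trt), b


@pytest.fixture
def toy_network():
    """Tiny hand-built weighted network for exact score checks."""
    g = nx.Graph()
    edges = [("A", "B"), ("B", "C"), ("C", "D"), ("B", "D"), ("D", "E")]
    g.add_edges_from(edges)
    z = {"A": 2.0, "B": 1.0, "C": 0.5, "D": -0.5, "E": 0.0}
    w = {("A", "B"): 3.0, ("B", "C"): 1.0, ("C", "D"): 0.2,
         ("B", "D"): 0.5, ("D", "E"): 0.1}
    return e.WeightedNetwork.from_weights(g, z, w)
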