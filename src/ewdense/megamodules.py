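"""Mega-modules: merging redundant modules, rescoring, hub identification.

Dense module searches seeded from every gene return many near-duplicate
modules.  Redundancy is removed by iteratively merging any pair of
significant modules whose gene overlap exceeds 80% of the smaller module,
restarting after each merge until no pair exceeds the threshold.  Each
resulting mega-module is rescored with the same score/standardization/
permutation machinery as the original search, and its hub genes are called
from within-module connectivity and eigenvector centrality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._sampling import spawn_rng
from .preprocess import bh_qvalues
from .search import Module, WeightedNetwork, _edge_key, module_raw_score, standardize_score

__all__ = [
    "MegaModule",
    "percent_overlap",
    "merge_modules",
    "score_megamodules",
    "module_centralities",
    "call_hubs",
]

log = logging.getLogger(__name__)

# deterministic cosmetic labels assigned by score rank
_LABELS = [
    "aliceblue", "bisque", "cadetblue", "coral", "darkorchid", "firebrick",
    "gainsboro", "honeydew", "ivory", "khaki", "lavender", "limegreen",
    "magenta", "navy", "olive", "peru", "plum", "salmon", "sienna", "teal",
    "thistle", "tomato", "turquoise", "violet", "wheat", "azure", "beige",
    "chartreuse", "crimson", "fuchsia", "gold", "indigo", "linen", "maroon",
    "orchid", "seagreen", "skyblue", "tan", "aquamarine", "chocolate",
]


@dataclass(frozen=True)
class MegaModule:
    """Union of merged significant modules with its own scores and hubs."""

    name: str
    constituents: tuple[int, ...]
    genes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    s_m: float = math.nan
    s_n: float = math.nan
    p: float | None = None
    q: float | None = None
    connectivity: dict[str, int] = field(default_factory=dict)
    eigencentrality: dict[str, float] = field(default_factory=dict)
    hubs: frozenset[str] = frozenset()

    @property
    def k(self) -> int:
        return len(self.genes)

    @property
    def m(self) -> int:
        return len(self.edges)


def percent_overlap(a: set[str] | frozenset[str], b: set[str] | frozenset[str]) -> float:
    """|A ∩ B| divided by the size of the smaller set; symmetric, in [0, 1]."""
    if not a or not b:
        raise ValueError("percent_overlap of an empty gene set")
    return len(set(a) & set(b)) / min(len(a), len(b))


def merge_modules(
    modules: list[Module],
    wn: WeightedNetwork,
    threshold: float = 0.8,
) -> list[MegaModule]:
    """Iteratively merge modules whose overlap strictly exceeds ``threshold``.

    At each pass the pair with the largest overlap merges (gene union with
    induced background edges) and the scan restarts; ties between pairs go
    to the larger summed S_n, then to the pair whose union holds the
    lexicographically smallest gene.  Terminates because every merge lowers
    the module count by one; afterwards no pair exceeds the threshold.
    Constituent module indices refer to the input ordering.
    """
    if not modules:
        return []
    work = [
        {"ids": {i}, "genes": set(mo.genes), "sn": mo.s_n}
        for i, mo in enumerate(modules)
    ]
    n = len(work)
    ov = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ov[i, j] = percent_overlap(work[i]["genes"], work[j]["genes"])
    alive = [True] * n
    while True:
        best = None
        for i in range(len(work)):
            if not alive[i]:
                continue
            for j in range(i + 1, len(work)):
                if not alive[j]:
                    continue
                o = ov[i, j]
                if o <= threshold:
                    continue
                key = (
                    o,
                    work[i]["sn"] + work[j]["sn"],
                    _neg_min_gene(work[i]["genes"] | work[j]["genes"]),
                )
                if best is None or key > best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        merged = {
            "ids": work[i]["ids"] | work[j]["ids"],
            "genes": work[i]["genes"] | work[j]["genes"],
            "sn": work[i]["sn"] + work[j]["sn"],
        }
        alive[i] = alive[j] = False
        work.append(merged)
        alive.append(True)
        k = len(work) - 1
        grown = np.zeros((k + 1, k + 1))
        grown[:k, :k] = ov
        ov = grown
        for t in range(k):
            if alive[t]:
                ov[min(t, k), max(t, k)] = percent_overlap(
                    work[t]["genes"], merged["genes"]
                )
    out = []
    for i, entry in enumerate(work):
        if not alive[i]:
            continue
        genes = frozenset(entry["genes"])
        edges = frozenset(
            _edge_key(u, v)
            for u in genes
            for v in wn.adj.get(u, ())
            if v in genes and u < v
        )
        out.append(MegaModule(
            name="", constituents=tuple(sorted(entry["ids"])),
            genes=genes, edges=edges,
        ))
    log.info("merged %d significant modules into %d mega-modules",
             len(modules), len(out))
    return out


class _neg_min_gene(str):
    """min gene wrapped so that max() over keys prefers the smaller symbol."""

    def __new__(cls, genes):
        return super().__new__(cls, min(genes))

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def score_megamodules(
    mms: list[MegaModule],
    wn: WeightedNetwork,
    b: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.05,
) -> list[MegaModule]:
    """Score, standardize and permutation-test each mega-module.

    Applies exactly the module-search machinery to the merged gene sets:
    raw score over the induced edges, analytic standardization, empirical p
    against ``b`` random same-(k, m) modules, BH q across mega-modules.
    Names are assigned from a fixed label list by descending MM-S_n.
    """
    if not mms:
        return []
    rng = spawn_rng(seed, "megamodule-significance")
    scored = []
    pvals = []
    for mm in mms:
        s_m = module_raw_score(mm.genes, mm.edges, wn)
        s_n = standardize_score(s_m, mm.k, mm.m, wn)
        draws = wn.null_raw_scores(mm.k, mm.m, b, rng)
        p = (1.0 + int((draws >= s_m).sum())) / (b + 1.0)
        scored.append((mm, s_m, s_n))
        pvals.append(p)
    qvals = bh_qvalues(np.array(pvals))
    order = sorted(
        range(len(scored)), key=lambda i: (-scored[i][2], scored[i][0].constituents)
    )
    named = [None] * len(scored)
    for rank, i in enumerate(order):
        mm, s_m, s_n = scored[i]
        name = (_LABELS[rank] if rank < len(_LABELS)
                else f"megamodule{rank + 1}")
        hub_info = module_centralities(mm.genes, mm.edges) if mm.m > 0 else ({}, {})
        hubs = call_hubs(*hub_info) if mm.m > 0 else frozenset()
        named[i] = MegaModule(
            name=name, constituents=mm.constituents, genes=mm.genes,
            edges=mm.edges, s_m=s_m, s_n=s_n,
            p=float(pvals[i]), q=float(qvals[i]),
            connectivity=hub_info[0], eigencentrality=hub_info[1], hubs=hubs,
        )
    sig = sum(1 for mm in named if mm.q < q_threshold)
    log.info("mega-module scoring: %d/%d at q<%g", sig, len(named), q_threshold)
    return named


def module_centralities(
    genes: frozenset[str], edges: frozenset[tuple[str, str]]
) -> tuple[dict[str, int], dict[str, float]]:
    """Within-module connectivity and eigenvector centrality per gene.

    Connectivity k_i is the degree inside the induced subgraph.
    Eigencentrality is the leading eigenvector of the induced adjacency,
    computed by power iteration on A + I (the shift breaks the period-2
    oscillation on bipartite subgraphs without changing the Perron vector),
    tolerance 1e-10, normalized so the maximum is 1.  On a disconnected
    subgraph the dominant component carries the mass (logged).
    """
    if not edges:
        raise ValueError("edgeless mega-module has no centralities")
    nodes = sorted(genes)
    pos = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v in edges:
        a[pos[u], pos[v]] = 1.0
        a[pos[v], pos[u]] = 1.0
    deg = a.sum(axis=1).astype(int)
    if (deg == 0).any():
        log.info("disconnected mega-module subgraph: %d isolated members",
                 int((deg == 0).sum()))
    x = np.full(n, 1.0 / math.sqrt(n))
    shifted = a + np.eye(n)
    for _ in range(100_000):
        nxt = shifted @ x
        nxt /= np.linalg.norm(nxt)
        if np.abs(nxt - x).max() < 1e-10:
            x = nxt
            break
        x = nxt
    ec = x / x.max()
    connectivity = {g: int(deg[pos[g]]) for g in nodes}
    eigencentrality = {g: float(ec[pos[g]]) for g in nodes}
    return connectivity, eigencentrality


def call_hubs(
    connectivity: dict[str, int],
    eigencentrality: dict[str, float],
    ec_threshold: float = 0.2,
) -> frozenset[str]:
    """Hub genes: EC > 0.2 and connectivity at or above the module's Q3.

    Q3 is the 75th percentile of the within-module degree vector with
    linear interpolation between order statistics.
    """
    if not connectivity:
        return frozenset()
    q3 = float(np.quantile(list(connectivity.values()), 0.75))
    return frozenset(
        g for g, kk in connectivity.items()
        if eigencentrality.get(g, 0.0) > ec_threshold and kk >= q3
    )
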