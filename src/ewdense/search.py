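"""Edge-weighted dense module search.

The search integrates three data sources on one background graph:

* node weights ``z_i = Φ⁻¹(1 − p_i)`` from gene-level GWAS p-values, so
  stronger association means larger z;
* edge weights ``w_e = |atanh(r_trt) − atanh(r_ctrl)| / sqrt(1/(n_t−3) +
  1/(n_c−3))`` — the Fisher-z standardized absolute difference of the two
  genes' expression correlation between treatment and control strain
  panels, so stronger differential co-expression means larger w;
* a balance factor ``λ = mean|w| / (mean|z| + mean|w|)`` fixed once from
  the full weight populations, equalizing the expected per-element
  contribution of nodes and edges to the module score.

A module of k genes with m induced edges scores

    S_m = λ·(Σ z_i)/√k + (1−λ)·(Σ w_e)/√m        (edge term 0 when m = 0)

and is standardized against same-size random modules, either analytically
(treating member weights as i.i.d. draws from the background populations)
or by Monte Carlo.  Greedy growth from every seed gene admits the neighbor
that maximizes the standardized score S_n as long as it improves S_n by at
least the growth rate (0.5% by default); permutation significance compares
each module's raw score with random same-(k, m) draws, with
Benjamini–Hochberg control across modules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._sampling import spawn_rng, subset_sums
from .containers import ExpressionPanel, GwasGeneStats
from .preprocess import bh_qvalues

__all__ = [
    "SearchParams",
    "Module",
    "WeightedNetwork",
    "node_weights",
    "edge_weights",
    "compute_lambda",
    "module_raw_score",
    "standardize_score",
    "greedy_search",
    "search_all",
    "module_significance",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchParams:
    """Tuning knobs of the greedy search and its null model."""

    growth_rate: float = 0.005
    neighbor_distance: int = 1
    min_module_size: int = 5
    standardization: str = "analytic"
    permutations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be > 0")
        if self.neighbor_distance < 1:
            raise ValueError("neighbor_distance must be >= 1")
        if self.standardization not in ("analytic", "montecarlo"):
            raise ValueError(f"unknown standardization {self.standardization!r}")
        if self.standardization == "montecarlo" and self.permutations < 100:
            raise ValueError("montecarlo standardization needs >= 100 permutations")


@dataclass(frozen=True)
class Module:
    """A connected gene set with its induced edges and scores."""

    genes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    seed_gene: str
    s_m: float
    s_n: float
    p: float | None = None
    q: float | None = None

    @property
    def k(self) -> int:
        return len(self.genes)

    @property
    def m(self) -> int:
        return len(self.edges)


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def node_weights(gwas: GwasGeneStats, eps: float = 1e-16) -> pd.Series:
    """z_i = Φ⁻¹(1 − p_i), the upper-tail normal quantile of the GWAS p.

    p-values are clipped into [eps, 1 − eps] so z stays finite; z is
    strictly decreasing in p.
    """
    p = gwas.p.to_numpy(dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("GWAS p-values must lie in (0, 1]")
    z = stats.norm.isf(np.clip(p, eps, 1.0 - eps))
    return pd.Series(z, index=gwas.p.index, name="z")


def edge_weights(
    ctrl: ExpressionPanel,
    trt: ExpressionPanel,
    background: nx.Graph,
    mode: str = "fisher",
) -> dict[tuple[str, str], float]:
    """Differential co-expression weight per background edge.

    ``fisher`` (default): |atanh(r_t) − atanh(r_c)| / sqrt(1/(n_t−3) +
    1/(n_c−3)), correlations clipped to ±(1 − 1e-12) first — a z-like scale
    commensurate with the node weights.  ``raw``: plain |r_t − r_c|.
    """
    if mode not in ("fisher", "raw"):
        raise ValueError(f"unknown edge weight mode {mode!r}")
    n_c, n_t = ctrl.n_strains, trt.n_strains
    if min(n_c, n_t) <= 3:
        raise ValueError("need more than 3 strains per condition")
    genes = list(background.nodes)
    missing = (set(genes) - ctrl.genes) | (set(genes) - trt.genes)
    if missing:
        raise ValueError(f"expression panels missing background genes: "
                         f"{sorted(missing)[:5]}...")
    zc = _standardized(ctrl.values.loc[genes].to_numpy(dtype=float))
    zt = _standardized(trt.values.loc[genes].to_numpy(dtype=float))
    pos = {g: i for i, g in enumerate(genes)}
    se = math.sqrt(1.0 / (n_t - 3) + 1.0 / (n_c - 3))
    clip = 1.0 - 1e-12
    w = {}
    for u, v in background.edges:
        i, j = pos[u], pos[v]
        r_c = float(np.clip(zc[i] @ zc[j] / n_c, -clip, clip))
        r_t = float(np.clip(zt[i] @ zt[j] / n_t, -clip, clip))
        if mode == "fisher":
            w[_edge_key(u, v)] = abs(math.atanh(r_t) - math.atanh(r_c)) / se
        else:
            w[_edge_key(u, v)] = abs(r_t - r_c)
    return w


def _standardized(x: np.ndarray) -> np.ndarray:
    """Rows centered and scaled to unit norm·√n; zero-variance rows → 0."""
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        log.info("%d zero-variance genes; their correlations treated as 0",
                 int(flat.sum()))
        sd[flat] = 1.0
    out = x / sd
    out[flat] = 0.0
    return out


def compute_lambda(z: np.ndarray, w: np.ndarray) -> float:
    """Balance λ = mean|w| / (mean|z| + mean|w|), so λ·mean|z| = (1−λ)·mean|w|."""
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    if z.size == 0 or w.size == 0:
        raise ValueError("need non-empty node and edge weight sets")
    mz, mw = np.abs(z).mean(), np.abs(w).mean()
    if mz + mw == 0:
        raise ValueError("all weights are zero; lambda undefined")
    return float(mw / (mz + mw))


@dataclass
class WeightedNetwork:
    """Background graph annotated with node weights, edge weights and λ.

    The weight moments (μ_z, σ_z over all nodes; μ_w, σ_w over all edges)
    are the population moments the analytic standardization draws from and
    are fixed at construction, before any search.
    """

    graph: nx.Graph
    z: dict[str, float]
    w: dict[tuple[str, str], float]
    lam: float
    mu_z: float
    sigma_z: float
    mu_w: float
    sigma_w: float
    adj: dict[str, dict[str, float]] = field(repr=False, default_factory=dict)
    _z_arr: np.ndarray = field(repr=False, default=None)
    _w_arr: np.ndarray = field(repr=False, default=None)
    _null_cache: dict = field(repr=False, default_factory=dict)

    @classmethod
    def build(
        cls,
        background: nx.Graph,
        gwas: GwasGeneStats,
        ctrl: ExpressionPanel,
        trt: ExpressionPanel,
        edge_weight_mode: str = "fisher",
        eps: float = 1e-16,
    ) -> "WeightedNetwork":
        z = node_weights(gwas, eps=eps)
        missing = set(background.nodes) - set(z.index)
        if missing:
            raise ValueError(f"GWAS missing background genes: "
                             f"{sorted(missing)[:5]}...")
        w = edge_weights(ctrl, trt, background, mode=edge_weight_mode)
        return cls.from_weights(
            background, {g: float(z[g]) for g in background.nodes}, w
        )

    @classmethod
    def from_weights(
        cls,
        background: nx.Graph,
        z: dict[str, float],
        w: dict[tuple[str, str], float],
    ) -> "WeightedNetwork":
        z_arr = np.array([z[g] for g in background.nodes], dtype=float)
        w_arr = np.array(
            [w[_edge_key(u, v)] for u, v in background.edges], dtype=float
        )
        sigma_z = float(z_arr.std())
        sigma_w = float(w_arr.std())
        if sigma_z == 0 or sigma_w == 0:
            raise ValueError("degenerate weight population (zero variance)")
        adj: dict[str, dict[str, float]] = {g: {} for g in background.nodes}
        for u, v in background.edges:
            wv = w[_edge_key(u, v)]
            adj[u][v] = wv
            adj[v][u] = wv
        return cls(
            graph=background,
            z=dict(z),
            w={_edge_key(u, v): w[_edge_key(u, v)] for u, v in background.edges},
            lam=compute_lambda(z_arr, w_arr),
            mu_z=float(z_arr.mean()),
            sigma_z=sigma_z,
            mu_w=float(w_arr.mean()),
            sigma_w=sigma_w,
            adj=adj,
            _z_arr=z_arr,
            _w_arr=w_arr,
        )

    # -- null machinery -----------------------------------------------------
    def null_raw_scores(
        self,
        k: int,
        m: int,
        b: int,
        rng: np.random.Generator,
        model: str = "unconstrained",
    ) -> np.ndarray:
        """Raw scores of ``b`` random modules of size (k, m).

        ``unconstrained`` (default): k nodes and m edges drawn uniformly
        without replacement, independently of each other — cheap and
        matches the i.i.d. assumption of the analytic standardization.
        ``connected``: random connected k-node subgraphs grown by uniform
        frontier expansion, scored with their own induced edges (m is
        ignored) — exchangeable with module-like gene sets at the price of
        more sampling work.
        """
        if model == "connected":
            return np.fromiter(
                (module_raw_score(*self.random_connected_module(k, rng), self)
                 for _ in range(b)),
                dtype=float, count=b,
            )
        if model != "unconstrained":
            raise ValueError(f"unknown null model {model!r}")
        sz = subset_sums(self._z_arr, k, b, rng)
        s = self.lam * sz / math.sqrt(k)
        if m > 0:
            sw = subset_sums(self._w_arr, m, b, rng)
            s = s + (1.0 - self.lam) * sw / math.sqrt(m)
        return s

    def random_connected_module(
        self, k: int, rng: np.random.Generator
    ) -> tuple[list[str], list[tuple[str, str]]]:
        """Random connected k-node subgraph grown by frontier expansion,
        with its induced edge list."""
        if not hasattr(self, "_node_list"):
            self._node_list = sorted(self.adj)
        nodes = self._node_list
        start = nodes[int(rng.integers(len(nodes)))]
        members = {start}
        frontier = sorted(self.adj[start])
        while len(members) < k and frontier:
            pick = frontier.pop(int(rng.integers(len(frontier))))
            members.add(pick)
            fresh = [nb for nb in self.adj[pick]
                     if nb not in members and nb not in frontier]
            frontier.extend(sorted(fresh))
        genes = sorted(members)
        edges = [
            _edge_key(u, v)
            for u in genes for v in self.adj[u] if v in members and u < v
        ]
        return genes, edges

    def null_moments(
        self, k: int, m: int, b: int, rng: np.random.Generator
    ) -> tuple[float, float]:
        """Monte-Carlo mean/sd of the raw score at size (k, m), cached."""
        key = (k, m)
        if key not in self._null_cache:
            draws = self.null_raw_scores(k, m, b, rng)
            self._null_cache[key] = (float(draws.mean()), float(draws.std(ddof=1)))
        return self._null_cache[key]


def module_raw_score(
    genes, edges, wn: WeightedNetwork
) -> float:
    """S_m = λ·(Σz)/√k + (1−λ)·(Σw)/√m; edge term absent when m = 0."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty module")
    k = len(genes)
    sz = sum(wn.z[g] for g in genes)
    s = wn.lam * sz / math.sqrt(k)
    edges = list(edges)
    if edges:
        sw = sum(wn.w[_edge_key(u, v)] for u, v in edges)
        s += (1.0 - wn.lam) * sw / math.sqrt(len(edges))
    return float(s)


def standardize_score(
    s_m: float,
    k: int,
    m: int,
    wn: WeightedNetwork,
    method: str = "analytic",
    b: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Standardize a raw score against same-(k, m) random modules.

    ``analytic`` treats the member weights as i.i.d. draws from the
    background populations; because S_m divides each sum by √k (resp. √m),
    the null mean is λ√k·μ_z + (1−λ)√m·μ_w while the null s.d. is the
    size-free sqrt(λ²σ_z² + (1−λ)²σ_w²).  ``montecarlo`` estimates both
    moments from ``b`` random modules (cached per (k, m)).
    """
    if method == "analytic":
        mean = wn.lam * math.sqrt(k) * wn.mu_z
        if m > 0:
            mean += (1.0 - wn.lam) * math.sqrt(m) * wn.mu_w
        sd = math.sqrt(
            (wn.lam * wn.sigma_z) ** 2 + ((1.0 - wn.lam) * wn.sigma_w) ** 2
        )
    elif method == "montecarlo":
        if rng is None:
            raise ValueError("montecarlo standardization needs an rng")
        mean, sd = wn.null_moments(k, m, b, rng)
    else:
        raise ValueError(f"unknown standardization {method!r}")
    if sd == 0:
        raise ValueError("null standard deviation is zero")
    return (s_m - mean) / sd


# ---------------------------------------------------------------------------
# greedy growth

def _analytic_sn(wn, sum_z, sum_w, k, m):
    s = wn.lam * sum_z / math.sqrt(k)
    mean = wn.lam * math.sqrt(k) * wn.mu_z
    if m > 0:
        s += (1.0 - wn.lam) * sum_w / math.sqrt(m)
        mean += (1.0 - wn.lam) * math.sqrt(m) * wn.mu_w
    sd = math.sqrt((wn.lam * wn.sigma_z) ** 2 + ((1.0 - wn.lam) * wn.sigma_w) ** 2)
    return (s - mean) / sd


def greedy_search(
    wn: WeightedNetwork, seed_gene: str, params: SearchParams | None = None
) -> Module:
    """Grow one module from ``seed_gene`` by greedy seed-and-extend.

    At each step every background gene adjacent to the current module (at
    neighbor distance ≤ d; with the default d = 1 this is the immediate
    frontier) is evaluated with all of its edges into the module.  The
    candidate maximizing the standardized score is admitted if it improves
    S_n by the growth rate r: S_n(new) ≥ S_n(old)·(1 + r) when S_n(old) > 0,
    or S_n(new) ≥ S_n(old) + |S_n(old)|·r otherwise (the multiplicative rule
    is ill-posed at non-positive scores).  Ties go to the higher node
    weight, then to the lexicographically smaller symbol.
    """
    params = params or SearchParams()
    if seed_gene not in wn.adj:
        raise KeyError(f"seed gene {seed_gene!r} not in background network")
    members = {seed_gene}
    sum_z = wn.z[seed_gene]
    sum_w = 0.0
    k, m = 1, 0
    # frontier bookkeeping: candidate -> (weight sum into module, edge count)
    cand: dict[str, list] = {}

    def absorb(gene: str) -> None:
        for nb, wv in wn.adj[gene].items():
            if nb in members:
                continue
            entry = cand.get(nb)
            if entry is None:
                cand[nb] = [wv, 1]
            else:
                entry[0] += wv
                entry[1] += 1
        if params.neighbor_distance > 1:
            _extend_frontier(wn, gene, members, cand, params.neighbor_distance)

    if params.standardization == "montecarlo":
        mc_rng = spawn_rng(params.seed, "mc-standardize")

        def sn_of(sz, sw, kk, mm):
            s = wn.lam * sz / math.sqrt(kk)
            if mm > 0:
                s += (1.0 - wn.lam) * sw / math.sqrt(mm)
            mean, sd = wn.null_moments(kk, mm, params.permutations, mc_rng)
            return (s - mean) / sd
    else:
        def sn_of(sz, sw, kk, mm):
            return _analytic_sn(wn, sz, sw, kk, mm)

    absorb(seed_gene)
    s_n = sn_of(sum_z, sum_w, k, m)
    while cand:
        best = None
        for gene, (w_in, m_in) in cand.items():
            sn_new = sn_of(sum_z + wn.z[gene], sum_w + w_in,
                           k + 1, m + m_in)
            key = (sn_new, wn.z[gene], _RevStr(gene))
            if best is None or key > best[0]:
                best = (key, gene, w_in, m_in, sn_new)
        _, gene, w_in, m_in, sn_new = best
        if s_n > 0:
            ok = sn_new >= s_n * (1.0 + params.growth_rate)
        else:
            ok = sn_new >= s_n + abs(s_n) * params.growth_rate
        if not ok:
            break
        members.add(gene)
        sum_z += wn.z[gene]
        sum_w += w_in
        k += 1
        m += m_in
        s_n = sn_new
        del cand[gene]
        absorb(gene)
    edges = frozenset(
        _edge_key(u, v)
        for u in members
        for v, _ in wn.adj[u].items()
        if v in members and u < v
    )
    s_m = module_raw_score(members, edges, wn)
    return Module(frozenset(members), edges, seed_gene, s_m,
                  sn_of(sum_z, sum_w, k, m))


class _RevStr(str):
    """Orders strings in reverse so that max() prefers the smaller symbol."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def _extend_frontier(wn, gene, members, cand, d):
    # BFS to depth d from the newly absorbed gene; far candidates join the
    # frontier with zero edges into the module until a real edge appears.
    seen = {gene}
    layer = [gene]
    for _ in range(d - 1):
        nxt = []
        for u in layer:
            for v in wn.adj[u]:
                if v in seen or v in members:
                    continue
                seen.add(v)
                nxt.append(v)
                cand.setdefault(v, [0.0, 0])
        layer = nxt


def search_all(
    wn: WeightedNetwork, params: SearchParams | None = None
) -> list[Module]:
    """One greedy module per seed gene, smallest modules dropped.

    Modules of size below ``min_module_size`` are discarded; the rest are
    returned sorted by (S_n descending, seed symbol).
    """
    params = params or SearchParams()
    modules = []
    for seed_gene in sorted(wn.adj):
        mod = greedy_search(wn, seed_gene, params)
        if mod.k >= params.min_module_size:
            modules.append(mod)
    modules.sort(key=lambda mo: (-mo.s_n, mo.seed_gene))
    log.info("greedy search: %d/%d seeds produced modules of size >= %d",
             len(modules), len(wn.adj), params.min_module_size)
    return modules


def module_significance(
    modules: list[Module],
    wn: WeightedNetwork,
    b: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.05,
    null_model: str = "unconstrained",
) -> tuple[list[Module], list[Module]]:
    """Permutation p and BH q per module; returns (all, significant).

    Each module's raw score is compared with ``b`` random modules of the
    same (k, m) — by default k genes and m edges drawn uniformly from the
    background; ``null_model='connected'`` draws random connected k-node
    subgraphs instead — using the (1 + exceedances)/(b + 1) estimator.
    q is Benjamini–Hochberg across all modules; significant = {q < 0.05}.
    """
    if not modules:
        return [], []
    rng = spawn_rng(seed, "module-significance")
    draws_cache: dict[tuple, np.ndarray] = {}
    pvals = []
    for mod in modules:
        key = (mod.k,) if null_model == "connected" else (mod.k, mod.m)
        if key not in draws_cache:
            draws_cache[key] = wn.null_raw_scores(mod.k, mod.m, b, rng,
                                                  model=null_model)
        exceed = int((draws_cache[key] >= mod.s_m).sum())
        pvals.append((1.0 + exceed) / (b + 1.0))
    qvals = bh_qvalues(np.array(pvals))
    annotated = [
        replace(mod, p=float(p), q=float(q))
        for mod, p, q in zip(modules, pvals, qvals)
    ]
    significant = [mo for mo in annotated if mo.q < q_threshold]
    log.info("module significance: %d/%d modules at q<%g",
             len(significant), len(annotated), q_threshold)
    return annotated, significant
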