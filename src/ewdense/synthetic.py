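"""Synthetic inputs with planted structure for the full pipeline.

Generates the four data sources the analysis consumes — a scale-free
protein-interaction graph, gene-level GWAS p-values, two-condition
strain-panel expression, and probe-level S-scores — with a known planted
gene set so that every downstream stage can be scored against ground truth.

Default parameters mirror the study conditions the pipeline is meant for:
a ~30-strain recombinant-inbred panel measured under control and acute
ethanol treatment, a few-thousand-gene interaction background, and GWAS
signal that partially covers the planted co-expression module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from ._sampling import spawn_rng
from .containers import ExpressionPanel, GwasGeneStats, SScorePanel

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticBundle",
    "generate_ppi",
    "generate_gwas",
    "generate_expression",
    "generate_sscores",
    "generate_bundle",
]

log = logging.getLogger(__name__)

_PPI_STREAM = 11
_GWAS_STREAM = 12
_GWAS_VALID_STREAM = 13
_EXPR_STREAM = 14
_SSCORE_STREAM = 15
_BASELINE_STREAM = 16
_PROBE_OFFSET_STREAM = 17


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the reference study conditions."""

    n_genes: int = 2000
    attach_m: int = 3
    n_strains_ctrl: int = 30
    n_strains_trt: int = 30
    planted_size: int = 50
    planted_density: float = 0.25
    gwas_alpha: float = 0.1
    rho_base: float = 0.1
    delta_rho: float = 0.6
    sscore_shift: float = 3.0
    probesets_per_gene: int = 2
    region: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.planted_size > self.n_genes:
            raise ValueError("planted_size exceeds n_genes")
        if not (0.0 <= self.planted_density <= 1.0):
            raise ValueError("planted_density outside [0, 1]")
        if not (0.0 < self.gwas_alpha <= 1.0):
            raise ValueError("gwas_alpha outside (0, 1]")
        if abs(self.rho_base) >= 1 or abs(self.rho_base + self.delta_rho) >= 1:
            raise ValueError("correlations must stay inside (-1, 1)")
        if min(self.n_strains_ctrl, self.n_strains_trt) < 4:
            raise ValueError("need at least 4 strains per condition")
        if self.probesets_per_gene < 1:
            raise ValueError("probesets_per_gene must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    planted_genes: frozenset[str]
    config: SyntheticConfig
    seed: int

    def __post_init__(self):
        universe = set(gene_symbols(self.config.n_genes))
        if not set(self.planted_genes) <= universe:
            raise ValueError("planted genes outside the generated universe")


def gene_symbols(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def strain_names(n: int) -> list[str]:
    return [f"BXD{i:03d}" for i in range(1, n + 1)]


def generate_ppi(config: SyntheticConfig) -> tuple[nx.Graph, SyntheticTruth]:
    """Scale-free background graph with a planted dense connected subgraph.

    The bulk topology is Barabási–Albert preferential attachment (matching
    the heavy-tailed degree structure of curated protein-interaction maps);
    extra edges are then added among a random planted gene set until its
    induced edge density reaches ``planted_density``, keeping it connected.
    """
    cfg = config
    rng = spawn_rng(cfg.seed, _PPI_STREAM)
    if cfg.planted_size < 2 and cfg.planted_density > 0:
        raise ValueError(
            "planted_density > 0 infeasible for planted_size < 2"
        )
    symbols = gene_symbols(cfg.n_genes)
    g = nx.barabasi_albert_graph(
        cfg.n_genes, cfg.attach_m, seed=int(rng.integers(2**31))
    )
    g = nx.relabel_nodes(g, dict(enumerate(symbols)))

    planted = sorted(rng.choice(symbols, size=cfg.planted_size, replace=False))
    if cfg.planted_size >= 2:
        _densify(g, planted, cfg.planted_density, rng)
    truth = SyntheticTruth(frozenset(planted), cfg, cfg.seed)
    return g, truth


def _densify(g: nx.Graph, planted: list[str], density: float, rng) -> None:
    s = len(planted)
    max_edges = s * (s - 1) // 2
    need = max(math.ceil(density * max_edges), s - 1)
    # random spanning tree over the planted genes guarantees connectivity
    order = list(rng.permutation(planted))
    for i, v in enumerate(order[1:], start=1):
        u = order[int(rng.integers(0, i))]
        g.add_edge(u, v)
    sub = g.subgraph(planted)
    missing = [
        (planted[i], planted[j])
        for i in range(s)
        for j in range(i + 1, s)
        if not sub.has_edge(planted[i], planted[j])
    ]
    deficit = need - sub.number_of_edges()
    if deficit > 0:
        pick = rng.choice(len(missing), size=deficit, replace=False)
        g.add_edges_from(missing[k] for k in pick)


def generate_gwas(
    truth: SyntheticTruth,
    alpha: float,
    seed: int,
    study: str = "synthetic_gwas",
    signal_genes: frozenset[str] | None = None,
) -> GwasGeneStats:
    """Gene-level p-values: Beta(alpha, 1) on signal genes, uniform elsewhere.

    ``alpha`` = 1 recovers the global null; small ``alpha`` concentrates
    planted p-values near zero.  ``signal_genes`` defaults to the full
    planted set and lets a validation study cover only part of it.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha outside (0, 1]")
    rng = np.random.default_rng([int(seed), _GWAS_STREAM])
    symbols = gene_symbols(truth.config.n_genes)
    signal = truth.planted_genes if signal_genes is None else signal_genes
    p = rng.uniform(size=len(symbols))
    mask = np.fromiter((s in signal for s in symbols), dtype=bool, count=len(symbols))
    p[mask] = rng.beta(alpha, 1.0, size=int(mask.sum()))
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    return GwasGeneStats(study, pd.Series(p, index=symbols, name="p"))


def generate_expression(
    truth: SyntheticTruth, config: SyntheticConfig | None = None
) -> tuple[ExpressionPanel, ExpressionPanel]:
    """Control and treatment strain panels with planted differential co-expression.

    A single latent factor shared by all genes sets the baseline pairwise
    correlation ``rho_base`` in both conditions; in the treatment condition
    the planted genes additionally load on a second latent factor so their
    pairwise correlation becomes ``rho_base + delta_rho``.  The factor
    construction keeps the implied covariance positive semi-definite for any
    admissible target.  Values are shifted onto an RMA-like scale (per-gene
    baseline ~ N(8, 1)) which leaves all correlations untouched.
    """
    cfg = truth.config if config is None else config
    rho_c = cfg.rho_base
    rho_t = cfg.rho_base + cfg.delta_rho
    if rho_c < 0 or rho_t < 0 or rho_c >= 1 or rho_t >= 1:
        raise ValueError(
            "factor construction infeasible: correlations must lie in [0, 1)"
        )
    symbols = gene_symbols(cfg.n_genes)
    planted_mask = np.fromiter(
        (s in truth.planted_genes for s in symbols), dtype=bool, count=len(symbols)
    )
    baseline = spawn_rng(cfg.seed, _BASELINE_STREAM).normal(8.0, 1.0, len(symbols))
    rng = spawn_rng(cfg.seed, _EXPR_STREAM)

    panels = []
    for condition, n_strains in (
        ("control", cfg.n_strains_ctrl),
        ("treatment", cfg.n_strains_trt),
    ):
        shared = rng.normal(size=n_strains)
        extra = rng.normal(size=n_strains)
        noise = rng.normal(size=(len(symbols), n_strains))
        x = np.empty_like(noise)
        # background genes: rho_base in both conditions
        a_bg = math.sqrt(rho_c)
        x[~planted_mask] = a_bg * shared + math.sqrt(1 - rho_c) * noise[~planted_mask]
        if condition == "control" or cfg.delta_rho <= 0:
            rho = rho_c if condition == "control" else rho_t
            a = math.sqrt(rho)
            x[planted_mask] = a * shared + math.sqrt(1 - rho) * noise[planted_mask]
        else:
            b = math.sqrt(cfg.delta_rho)
            x[planted_mask] = (
                a_bg * shared
                + b * extra
                + math.sqrt(1 - rho_t) * noise[planted_mask]
            )
        values = pd.DataFrame(
            baseline[:, None] + x,
            index=symbols,
            columns=strain_names(n_strains),
        )
        panels.append(ExpressionPanel(cfg.region, condition, values))
    return panels[0], panels[1]


def generate_sscores(
    truth: SyntheticTruth, config: SyntheticConfig | None = None
) -> tuple[SScorePanel, pd.Series]:
    """Per-probeset, per-strain S-scores plus the probeset → gene map.

    Probesets of planted (ethanol-responsive) genes draw
    N(``sscore_shift``, 1); all others draw N(0, 1), the null reference of
    the S-score statistic.  Every gene gets ``probesets_per_gene`` probesets.
    """
    cfg = truth.config if config is None else config
    rng = spawn_rng(cfg.seed, _SSCORE_STREAM)
    symbols = gene_symbols(cfg.n_genes)
    probesets, genes = [], []
    for g in symbols:
        for j in range(1, cfg.probesets_per_gene + 1):
            probesets.append(f"{g}_ps{j}")
            genes.append(g)
    shift = np.where(
        np.fromiter((g in truth.planted_genes for g in genes), bool, len(genes)),
        cfg.sscore_shift,
        0.0,
    )
    n_strains = cfg.n_strains_ctrl
    values = rng.normal(size=(len(probesets), n_strains)) + shift[:, None]
    panel = SScorePanel(
        cfg.region,
        pd.DataFrame(values, index=probesets, columns=strain_names(n_strains)),
    )
    probe_map = pd.Series(genes, index=pd.Index(probesets, name="probeset"), name="gene")
    return panel, probe_map


@dataclass(frozen=True)
class SyntheticBundle:
    """One complete synthetic dataset, ready for the pipeline."""

    config: SyntheticConfig
    truth: SyntheticTruth
    ppi: nx.Graph = field(repr=False)
    gwas_discovery: GwasGeneStats = field(repr=False)
    gwas_validation: GwasGeneStats = field(repr=False)
    expr_ctrl: ExpressionPanel = field(repr=False)
    expr_trt: ExpressionPanel = field(repr=False)
    sscores: SScorePanel = field(repr=False)
    probe_map: pd.Series = field(repr=False)
    homolog_map: pd.Series = field(repr=False)
    probe_rma_ctrl: pd.DataFrame = field(repr=False, default=None)
    probe_rma_trt: pd.DataFrame = field(repr=False, default=None)


def generate_bundle(
    config: SyntheticConfig, validation_fraction: float = 0.5
) -> SyntheticBundle:
    """Full dataset: PPI, two GWAS, expression panels, S-scores and maps.

    The validation GWAS carries signal on a random ``validation_fraction``
    of the planted genes, emulating an independent study whose enriched
    genes only partially cover the planted module.  The homolog map is the
    identity on the synthetic universe so the mapping code path is exercised
    without changing symbols.
    """
    ppi, truth = generate_ppi(config)
    rng = spawn_rng(config.seed, _GWAS_VALID_STREAM)
    planted = sorted(truth.planted_genes)
    n_val = max(1, int(round(validation_fraction * len(planted)))) if planted else 0
    val_signal = frozenset(
        rng.choice(planted, size=n_val, replace=False)
    ) if planted else frozenset()
    gwas_disc = generate_gwas(
        truth, config.gwas_alpha, config.seed, study="discovery"
    )
    gwas_val = generate_gwas(
        truth,
        config.gwas_alpha,
        config.seed + 1,
        study="validation",
        signal_genes=val_signal,
    )
    expr_ctrl, expr_trt = generate_expression(truth)
    sscores, probe_map = generate_sscores(truth)
    symbols = gene_symbols(config.n_genes)
    homolog = pd.Series(symbols, index=pd.Index(symbols, name="source"), name="target")
    probe_ctrl, probe_trt = _probe_level_rma(
        config, probe_map, expr_ctrl, expr_trt
    )
    return SyntheticBundle(
        config, truth, ppi, gwas_disc, gwas_val, expr_ctrl, expr_trt,
        sscores, probe_map, homolog, probe_ctrl, probe_trt,
    )


def _probe_level_rma(config, probe_map, expr_ctrl, expr_trt):
    """Expand gene-level panels to probeset rows with per-probeset offsets.

    Each probeset's RMA is its gene's value plus a constant offset, so the
    maximum-mean collapse deterministically recovers the highest-offset
    probeset per gene and correlations are untouched.
    """
    rng = spawn_rng(config.seed, _PROBE_OFFSET_STREAM)
    offsets = pd.Series(
        rng.uniform(-1.0, 1.0, size=len(probe_map)), index=probe_map.index
    )
    out = []
    for panel in (expr_ctrl, expr_trt):
        mat = panel.values.loc[probe_map.to_numpy()].to_numpy()
        out.append(pd.DataFrame(
            mat + offsets.to_numpy()[:, None],
            index=probe_map.index,
            columns=panel.values.columns,
        ))
    return out[0], out[1]


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Full-null study conditions: no GWAS signal, no differential
    co-expression, no responsive probesets."""
    base = SyntheticConfig(
        gwas_alpha=1.0, delta_rho=0.0, sscore_shift=0.0, seed=seed
    )
    return replace(base, **overrides) if overrides else base
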