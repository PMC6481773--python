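"""From probe-level responsiveness to the background network.

The stages here mirror the standard preparation for an edge-weighted module
search: (1) call ethanol-responsive probesets from per-strain S-scores by
Fisher-combining two-sided normal p-values across the strain panel, with a
permutation empirical p and Benjamini–Hochberg q per region; (2) keep a
probeset if q < 0.1 in any region; (3) collapse to one probeset per gene by
maximum mean RMA; (4) map symbols through a homolog table; (5) intersect the
interaction graph with the GWAS and expression universes to form the
background network the module search runs on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._sampling import spawn_rng
from .containers import ExpressionPanel, SScorePanel

__all__ = [
    "fisher_combine",
    "responsive_calls",
    "filter_responsive",
    "collapse_probesets",
    "map_homologs",
    "build_background",
]

log = logging.getLogger(__name__)


def fisher_combine(pvals: Sequence[float]) -> tuple[float, float]:
    """Fisher's combined statistic −2·Σ ln p and its chi-square(2k) tail p."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    if (arr <= 0).any() or (arr > 1).any() or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in (0, 1]")
    stat = float(-2.0 * np.log(arr).sum())
    return stat, float(stats.chi2.sf(stat, df=2 * arr.size))


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


@dataclass(frozen=True)
class ResponsiveCalls:
    """Per-probeset, per-region responsiveness table.

    Columns: probeset, region, statistic, df, p_analytic, p_empirical, q.
    """

    table: pd.DataFrame

    def region(self, region: str) -> pd.DataFrame:
        return self.table[self.table["region"] == region]


def responsive_calls(
    panels: SScorePanel | Iterable[SScorePanel],
    n_perm: int = 1000,
    seed: int = 0,
) -> ResponsiveCalls:
    """Call responsive probesets per region from S-score panels.

    Per strain, the two-sided p of each S-score against its standard-normal
    null reference is computed; Fisher's method combines the strains into
    one statistic per probeset (df = 2 × strains).  The empirical p compares
    the observed statistic with ``n_perm`` column-wise permutations of the
    panel (S-scores shuffled across probesets independently within each
    strain), which breaks probeset identity while preserving each strain's
    score distribution.  q is Benjamini–Hochberg over empirical p within
    region.
    """
    if isinstance(panels, SScorePanel):
        panels = [panels]
    if n_perm < 100:
        log.warning("n_perm=%d is low for stable empirical p-values", n_perm)
    frames = []
    for panel in panels:
        values = panel.values.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError(f"non-finite S-score in region {panel.region}")
        n_probes, n_strains = values.shape
        if n_strains < 2:
            raise ValueError("need at least 2 strains per region")
        neglog = -2.0 * np.log(
            np.clip(2.0 * stats.norm.sf(np.abs(values)), 1e-300, 1.0)
        )
        observed = neglog.sum(axis=1)
        rng = spawn_rng(seed, "responsive", panel.region)
        exceed = np.zeros(n_probes, dtype=np.int64)
        for _ in range(n_perm):
            perm = rng.permuted(neglog, axis=0)
            exceed += perm.sum(axis=1) >= observed
        p_emp = (1.0 + exceed) / (n_perm + 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "probeset": panel.values.index,
                    "region": panel.region,
                    "statistic": observed,
                    "df": 2 * n_strains,
                    "p_analytic": stats.chi2.sf(observed, df=2 * n_strains),
                    "p_empirical": p_emp,
                    "q": bh_qvalues(p_emp),
                }
            )
        )
    return ResponsiveCalls(pd.concat(frames, ignore_index=True))


def filter_responsive(calls: ResponsiveCalls, q_threshold: float = 0.1) -> set[str]:
    """Probesets with q < threshold in at least one region (any-region rule)."""
    t = calls.table
    kept = set(t.loc[t["q"] < q_threshold, "probeset"])
    log.info(
        "responsive filter: %d/%d probesets at q<%g in any region",
        len(kept), t["probeset"].nunique(), q_threshold,
    )
    return kept


def collapse_probesets(
    panels: Mapping[str, pd.DataFrame],
    probe_map: pd.Series,
    region: str = "synthetic",
) -> tuple[dict[str, ExpressionPanel], pd.Series]:
    """One probeset per gene by maximum mean RMA across both conditions.

    ``panels`` maps condition → probeset × strain RMA matrix.  For every
    gene, the probeset with the highest mean RMA over all strains of the
    region (control and treatment pooled) supplies the gene's row in every
    condition; ties go to the lexicographically smallest probeset id.
    """
    if probe_map.index.has_duplicates:
        dup = probe_map.index[probe_map.index.duplicated()][0]
        raise ValueError(f"probeset {dup!r} maps to multiple genes")
    common = None
    for df in panels.values():
        idx = df.index
        common = idx if common is None else common.intersection(idx)
    common = common.intersection(probe_map.index)
    pooled = pd.concat([df.loc[common] for df in panels.values()], axis=1)
    means = pooled.mean(axis=1)
    pick = (
        pd.DataFrame({"gene": probe_map.loc[common], "mean_rma": means})
        .reset_index(names="probeset")
        .sort_values(["gene", "mean_rma", "probeset"],
                     ascending=[True, False, True])
        .groupby("gene", sort=True)
        .head(1)
    )
    chosen = pd.Series(pick["probeset"].to_numpy(), index=pick["gene"], name="probeset")
    out = {}
    for condition, df in panels.items():
        mat = df.loc[chosen.to_numpy()]
        mat.index = chosen.index
        out[condition] = ExpressionPanel(region, condition, mat)
    return out, chosen


def map_homologs(
    expr: pd.DataFrame, homolog: pd.Series
) -> pd.DataFrame:
    """Rename a genes × strains matrix through a homolog table.

    Unmapped genes are dropped.  If several source genes map to the same
    target symbol, the source with the higher mean RMA survives (logged).
    """
    if homolog.index.has_duplicates:
        raise ValueError("homolog table has duplicate source symbols")
    present = expr.index.intersection(homolog.index)
    if len(present) == 0:
        raise ValueError("no genes survive homolog mapping")
    mapped = expr.loc[present].copy()
    targets = homolog.loc[present]
    order = (
        pd.DataFrame({"target": targets.to_numpy(),
                      "mean_rma": mapped.mean(axis=1).to_numpy(),
                      "source": present})
        .sort_values(["target", "mean_rma", "source"],
                     ascending=[True, False, True])
    )
    dups = order.duplicated("target")
    if dups.any():
        log.info("homolog mapping: %d source genes lost to target collisions",
                 int(dups.sum()))
    keep = order[~dups]
    out = mapped.loc[keep["source"].to_numpy()]
    out.index = pd.Index(keep["target"].to_numpy(), name=expr.index.name)
    return out.sort_index()


def build_background(
    ppi: nx.Graph,
    gwas_genes: Iterable[str],
    expr_genes: Iterable[str],
) -> nx.Graph:
    """Induced interaction subgraph on PPI ∩ GWAS ∩ expression universes.

    Nodes that end up with induced degree 0 are removed — an isolated gene
    can never join an edge-weighted module.
    """
    keep = set(ppi.nodes) & set(gwas_genes) & set(expr_genes)
    if not keep:
        raise ValueError("empty intersection of PPI, GWAS and expression genes")
    g = ppi.subgraph(keep).copy()
    isolated = [n for n, d in g.degree() if d == 0]
    g.remove_nodes_from(isolated)
    log.info(
        "background network: %d nodes, %d edges (%d isolated nodes dropped)",
        g.number_of_nodes(), g.number_of_edges(), len(isolated),
    )
    if g.number_of_nodes() == 0:
        raise ValueError("background network empty after removing isolated nodes")
    return g
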