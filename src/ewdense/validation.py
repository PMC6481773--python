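"""Cross-GWAS validation and local over-representation analysis.

An independent GWAS validates the discovered mega-modules three ways:
counting its nominal genes (gene-wise p < 0.001) inside each mega-module
against random same-size gene sets; regressing each mega-module's mean
validation p-value on its standardized score; and testing pairwise
mega-module gene overlap with the hypergeometric tail.  Functional
over-representation of a gene set against GMT annotation sets is a plain
one-sided hypergeometric test with the filters p < 0.01, ≥3 hit genes and
≤1000 genes per set, Bonferroni-corrected within annotation category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Collection, Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._sampling import spawn_rng, subset_sums
from .containers import GwasGeneStats
from .megamodules import MegaModule

__all__ = [
    "NominalGeneSet",
    "nominal_genes",
    "overrep_test",
    "overrep_megamodules",
    "score_regression",
    "overlap_test",
    "ora_enrichment",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NominalGeneSet:
    """Genes below the nominal threshold of one validation study."""

    study: str
    threshold: float
    genes: frozenset[str]


def nominal_genes(
    gwas: GwasGeneStats,
    threshold: float = 0.001,
    restrict_to: Collection[str] | None = None,
) -> NominalGeneSet:
    """{g : p_g < threshold}, optionally intersected with the background."""
    sel = gwas.p[gwas.p < threshold].index
    genes = set(sel)
    if restrict_to is not None:
        genes &= set(restrict_to)
    return NominalGeneSet(gwas.study, threshold, frozenset(genes))


def overrep_test(
    module_genes: Collection[str],
    nominal: NominalGeneSet,
    background: Collection[str],
    b: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation p for nominal-gene overrepresentation in one gene set.

    Draws ``b`` uniform gene sets of the module's size from the background
    (without replacement within a draw) and reports
    (1 + #{draws with ≥ observed nominal count}) / (b + 1).
    """
    background = sorted(set(background))
    module_genes = set(module_genes)
    if len(module_genes) > len(background):
        raise ValueError("module larger than the background universe")
    nominal_in_bg = nominal.genes & set(background)
    observed = len(module_genes & nominal_in_bg)
    indicator = np.fromiter(
        (g in nominal_in_bg for g in background), float, len(background)
    )
    rng = spawn_rng(seed, "overrep")
    counts = subset_sums(indicator, len(module_genes), b, rng)
    return float((1.0 + (counts >= observed - 1e-9).sum()) / (b + 1.0))


def overrep_megamodules(
    mms: Iterable[MegaModule],
    nominal: NominalGeneSet,
    background: Collection[str],
    b: int = 10_000,
    seed: int = 0,
    bonferroni: str = "tested",
) -> pd.DataFrame:
    """Overrepresentation across a region's mega-modules.

    Only mega-modules containing more than one nominal gene are tested;
    the significance threshold is 0.05/n with n either the number of
    mega-modules actually tested (``bonferroni='tested'``, default) or all
    mega-modules in the region (``'all'``).
    """
    mms = list(mms)
    rows = []
    for i, mm in enumerate(mms):
        hits = mm.genes & nominal.genes
        if len(hits) <= 1:
            continue
        p = overrep_test(mm.genes, nominal, background, b=b, seed=seed + i)
        rows.append({
            "megamodule": mm.name, "k_g": mm.k,
            "nominal_hits": len(hits),
            "hit_genes": ";".join(sorted(hits)),
            "p_overrep": p,
        })
    df = pd.DataFrame(rows, columns=[
        "megamodule", "k_g", "nominal_hits", "hit_genes", "p_overrep"
    ])
    n = len(df) if bonferroni == "tested" else len(mms)
    df["threshold"] = 0.05 / max(n, 1)
    df["significant"] = df["p_overrep"] < df["threshold"]
    return df


def score_regression(
    mms: Iterable[MegaModule], validation: GwasGeneStats
) -> tuple[float, float]:
    """OLS of mega-module mean validation p on MM-S_n; returns (β, p).

    Each mega-module's mean p is taken over its genes that appear in the
    validation study (absences logged).  A negative β means higher-scoring
    mega-modules carry more significant validation p-values.  The per-region
    significance call applies Bonferroni over the three brain regions,
    α = 0.05/3 ≈ 0.017.
    """
    xs, ys = [], []
    lost = 0
    for mm in mms:
        present = [g for g in mm.genes if g in validation.p.index]
        lost += mm.k - len(present)
        if not present:
            continue
        xs.append(mm.s_n)
        ys.append(float(validation.p.loc[present].mean()))
    if lost:
        log.info("score regression: %d mega-module genes absent from %s",
                 lost, validation.study)
    if len(xs) < 3:
        raise ValueError("need at least 3 mega-modules for the regression")
    x = np.asarray(xs)
    if x.std() == 0:
        raise ValueError("zero variance in MM-S_n")
    fit = sm.OLS(np.asarray(ys), sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def overlap_test(
    genes_a: Collection[str] | int,
    genes_b: Collection[str] | int,
    n_background: int,
    overlap: int | None = None,
) -> float:
    """Hypergeometric tail P(X ≥ |A ∩ B|) for the gene overlap of two sets.

    Accepts either the gene sets themselves or their sizes plus an explicit
    ``overlap`` count.
    """
    if isinstance(genes_a, int):
        size_a, size_b = genes_a, genes_b
        if overlap is None:
            raise ValueError("overlap count required with set sizes")
    else:
        a, b = set(genes_a), set(genes_b)
        size_a, size_b = len(a), len(b)
        overlap = len(a & b)
    if size_a > n_background or size_b > n_background:
        raise ValueError("set larger than the background")
    return float(stats.hypergeom.sf(overlap - 1, n_background, size_a, size_b))


def ora_enrichment(
    query: Collection[str],
    gene_sets: Mapping[str, Collection[str]],
    universe: Collection[str],
    categories: Mapping[str, str] | None = None,
    p_max: float = 0.01,
    min_hits: int = 3,
    max_set_size: int = 1000,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in annotation sets.

    Per set: one-sided hypergeometric p of the overlap with the query
    against the universe.  Records are kept iff p < ``p_max``, at least
    ``min_hits`` genes overlap and the (universe-restricted) set has at most
    ``max_set_size`` genes.  The Bonferroni q multiplies p by the number of
    sets tested in the same category (capped at 1) and the table is sorted
    by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    categories = categories or {}
    n_per_category: dict[str, int] = {}
    prelim = []
    for name, members in gene_sets.items():
        members_u = set(members) & universe
        if not members_u:
            continue
        cat = categories.get(name, "default")
        n_per_category[cat] = n_per_category.get(cat, 0) + 1
        hits = sorted(query & members_u)
        p = float(stats.hypergeom.sf(
            len(hits) - 1, len(universe), len(members_u), len(query)
        ))
        prelim.append((cat, name, len(members_u), hits, p))
    rows = []
    for cat, name, set_size, hits, p in prelim:
        if p < p_max and len(hits) >= min_hits and set_size <= max_set_size:
            rows.append({
                "category": cat, "set_name": name, "set_size": set_size,
                "hits": len(hits), "p": p,
                "q_bonferroni": min(1.0, p * n_per_category[cat]),
                "hit_genes": ";".join(hits),
            })
    df = pd.DataFrame(rows, columns=[
        "category", "set_name", "set_size", "hits", "p", "q_bonferroni",
        "hit_genes",
    ])
    return df.sort_values("p", kind="stable").reset_index(drop=True)
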