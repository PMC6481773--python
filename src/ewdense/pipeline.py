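"""End-to-end pipeline driver.

Stage order: responsive-probeset calling → probeset collapse → homolog
mapping → background construction → weighted network → greedy module
search → permutation significance → mega-module merging and rescoring →
hub calling → cross-GWAS validation → optional functional enrichment.
Every stage draws from a named substream of the single pipeline seed and
writes plain-text artifacts plus a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as ewio
from .megamodules import merge_modules, score_megamodules
from .preprocess import (
    build_background,
    collapse_probesets,
    filter_responsive,
    map_homologs,
    responsive_calls,
)
from .search import SearchParams, WeightedNetwork, module_significance, search_all
from .synthetic import SyntheticBundle
from .validation import (
    nominal_genes,
    overrep_megamodules,
    ora_enrichment,
    score_regression,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_on_bundle"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of every stage, echoed into the output manifest."""

    input_dir: str = "."
    output_dir: str = "results"
    gmt_path: str | None = None
    responsive_q: float = 0.1
    responsive_perms: int = 1000
    growth_rate: float = 0.005
    neighbor_distance: int = 1
    min_module_size: int = 5
    standardization: str = "analytic"
    module_perms: int = 1000
    module_q: float = 0.05
    overlap_threshold: float = 0.8
    nominal_p: float = 0.001
    overrep_B: int = 10000
    overrep_bonferroni: str = "tested"
    ec_hub: float = 0.2
    edge_weight_mode: str = "fisher"
    seed: int = 0

    def __post_init__(self):
        for name in ("responsive_q", "module_q", "nominal_p",
                     "overlap_threshold", "ec_hub"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} outside (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


@dataclass
class PipelineResult:
    """In-memory handles to every stage output."""

    background: object
    weighted: WeightedNetwork
    modules: list
    significant: list
    megamodules: list
    overrep: pd.DataFrame
    regression: tuple[float, float] | None
    enrichment: pd.DataFrame | None
    responsive_probesets: set[str] = field(default_factory=set)
    manifest: dict = field(default_factory=dict)


def run_on_bundle(
    bundle: SyntheticBundle, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run every stage on an in-memory data bundle."""
    cfg = config or PipelineConfig()
    region = bundle.config.region

    calls = responsive_calls(bundle.sscores, n_perm=cfg.responsive_perms,
                             seed=cfg.seed)
    responsive = filter_responsive(calls, q_threshold=cfg.responsive_q)
    probe_map = bundle.probe_map[bundle.probe_map.index.isin(responsive)]
    if probe_map.empty:
        # nothing responsive is a meaningful outcome, not a malformed input
        log.warning("no responsive probesets at q<%g; empty result",
                    cfg.responsive_q)
        return _empty_result(cfg, region, len(responsive))
    panels, _chosen = collapse_probesets(
        {"control": bundle.probe_rma_ctrl.loc[
            bundle.probe_rma_ctrl.index.intersection(probe_map.index)],
         "treatment": bundle.probe_rma_trt.loc[
            bundle.probe_rma_trt.index.intersection(probe_map.index)]},
        probe_map, region=region,
    )
    mapped = {cond: map_homologs(panel.values, bundle.homolog_map)
              for cond, panel in panels.items()}
    from .containers import ExpressionPanel
    ctrl = ExpressionPanel(region, "control", mapped["control"])
    trt = ExpressionPanel(region, "treatment", mapped["treatment"])

    background = build_background(
        bundle.ppi, bundle.gwas_discovery.genes, set(ctrl.values.index)
    )
    wn = WeightedNetwork.build(
        background, bundle.gwas_discovery, ctrl, trt,
        edge_weight_mode=cfg.edge_weight_mode,
    )
    params = SearchParams(
        growth_rate=cfg.growth_rate,
        neighbor_distance=cfg.neighbor_distance,
        min_module_size=cfg.min_module_size,
        standardization=cfg.standardization,
        permutations=cfg.module_perms,
        seed=cfg.seed,
    )
    modules = search_all(wn, params)
    modules, significant = module_significance(
        modules, wn, b=cfg.module_perms, seed=cfg.seed,
        q_threshold=cfg.module_q,
    )
    mms = merge_modules(significant, wn, threshold=cfg.overlap_threshold)
    mms = score_megamodules(mms, wn, b=cfg.module_perms, seed=cfg.seed,
                            q_threshold=cfg.module_q)
    sig_mms = [mm for mm in mms if mm.q is not None and mm.q < cfg.module_q]

    nominal = nominal_genes(bundle.gwas_validation, threshold=cfg.nominal_p,
                            restrict_to=background.nodes)
    overrep = overrep_megamodules(
        sig_mms, nominal, background.nodes, b=cfg.overrep_B, seed=cfg.seed,
        bonferroni=cfg.overrep_bonferroni,
    )
    regression = None
    if len(sig_mms) >= 3:
        try:
            regression = score_regression(sig_mms, bundle.gwas_validation)
        except ValueError as exc:
            log.info("score regression skipped: %s", exc)

    enrichment = None
    if cfg.gmt_path:
        sets, _ = ewio.read_gmt(cfg.gmt_path)
        focus = overrep[overrep["significant"]]["megamodule"]
        query = set()
        for mm in sig_mms:
            if mm.name in set(focus):
                query |= set(mm.genes)
        if query:
            enrichment = ora_enrichment(query, sets, set(background.nodes))

    manifest = {
        "parameters": dataclasses.asdict(cfg),
        "region": region,
        "counts": {
            "responsive_probesets": len(responsive),
            "background_nodes": background.number_of_nodes(),
            "background_edges": background.number_of_edges(),
            "modules": len(modules),
            "significant_modules": len(significant),
            "megamodules": len(mms),
            "significant_megamodules": len(sig_mms),
            "nominal_validation_genes": len(nominal.genes),
        },
        "lambda": wn.lam,
    }
    return PipelineResult(
        background=background, weighted=wn, modules=modules,
        significant=significant, megamodules=mms, overrep=overrep,
        regression=regression, enrichment=enrichment,
        responsive_probesets=responsive, manifest=manifest,
    )


def _empty_result(cfg: PipelineConfig, region: str, n_responsive: int):
    import networkx as nx

    return PipelineResult(
        background=nx.Graph(), weighted=None, modules=[], significant=[],
        megamodules=[],
        overrep=pd.DataFrame(columns=["megamodule", "k_g", "nominal_hits",
                                      "hit_genes", "p_overrep", "threshold",
                                      "significant"]),
        regression=None, enrichment=None, responsive_probesets=set(),
        manifest={
            "parameters": dataclasses.asdict(cfg),
            "region": region,
            "counts": {"responsive_probesets": n_responsive,
                       "background_nodes": 0, "background_edges": 0,
                       "modules": 0, "significant_modules": 0,
                       "megamodules": 0, "significant_megamodules": 0,
                       "nominal_validation_genes": 0},
            "lambda": None,
        },
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Read a bundle from ``input_dir``, run all stages, write ``output_dir``."""
    try:
        bundle = ewio.read_bundle(config.input_dir)
    except FileNotFoundError as exc:
        raise RuntimeError(f"input stage: missing file {exc.filename}") from exc
    result = run_on_bundle(bundle, config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ewio.write_modules_table(result.modules, out / "modules.tsv")
    ewio.write_megamodule_table(
        result.megamodules, out / "megamodules.tsv",
        gwas_node=bundle.gwas_discovery, gwas_validation=bundle.gwas_validation,
    )
    result.overrep.to_csv(out / "overrepresentation.tsv", sep="\t", index=False)
    if result.enrichment is not None:
        result.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    report = dict(result.manifest)
    if result.regression is not None:
        report["regression"] = {"beta": result.regression[0],
                                "p": result.regression[1]}
    (out / "manifest.json").write_text(json.dumps(report, indent=2))
    log.info("pipeline complete: %s", out)
    return out
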