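"""Readers and writers for the pipeline's plain-text formats.

Everything is tab-separated text (plus GMT for annotation sets and JSON for
the truth file and manifest) so that intermediates diff cleanly.  Gene
symbols are upper-cased at ingest, following the human symbol convention;
collisions introduced by case-folding are logged.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionPanel, GwasGeneStats, SScorePanel
from .synthetic import SyntheticBundle, SyntheticConfig, SyntheticTruth

__all__ = [
    "read_edge_list",
    "read_gwas_table",
    "read_matrix",
    "read_homolog_map",
    "read_gmt",
    "write_bundle",
    "read_bundle",
    "write_modules_table",
    "write_megamodule_table",
]

log = logging.getLogger(__name__)

_SIF_RELATION = re.compile(r"^[a-z_-]{1,16}$")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Undirected simple graph from a two-column TSV or SIF edge list.

    The SIF dialect (``node relation node``) is auto-detected when every
    line has ≥3 fields and the middle field looks like a short lowercase
    relation token.  Self loops and duplicate edges are dropped (counts
    logged); symbols are upper-cased.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns")
            rows.append(fields)
    if not rows:
        raise ValueError(f"{path}: empty edge list")
    # SIF dialect: "node relation node" with a short lowercase relation token
    is_sif = all(
        len(r) >= 3 and _SIF_RELATION.match(r[1]) is not None for r in rows
    )
    a_col, b_col = (0, 2) if is_sif else (0, 1)
    if is_sif:
        log.info("%s: SIF dialect detected", path)
    g = nx.Graph()
    self_loops = dup = 0
    for r in rows:
        u, v = r[a_col].upper(), r[b_col].upper()
        if u == v:
            self_loops += 1
            continue
        if g.has_edge(u, v):
            dup += 1
            continue
        g.add_edge(u, v)
    if self_loops or dup:
        log.info("%s: dropped %d self loops, %d duplicate edges",
                 path, self_loops, dup)
    if g.number_of_edges() == 0:
        raise ValueError(f"{path}: no usable edges")
    return g


def read_gwas_table(path: str | Path, study: str | None = None) -> GwasGeneStats:
    """GWAS table: headered TSV with ``gene`` and ``p`` columns."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or "p" not in df.columns:
        raise ValueError(f"{path}: need 'gene' and 'p' columns")
    genes = df["gene"].astype(str).str.upper()
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene symbol {dup!r}")
    p = pd.to_numeric(df["p"], errors="coerce")
    bad = p.isna() | (p <= 0) | (p > 1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
        raise ValueError(f"{path}: invalid p-value at line {row}")
    return GwasGeneStats(study or path.stem, pd.Series(p.to_numpy(), index=genes))


def read_matrix(path: str | Path, uppercase_index: bool = True) -> pd.DataFrame:
    """Row-labelled numeric TSV matrix (genes or probesets × strains)."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    if uppercase_index:
        df.index = df.index.astype(str).str.upper()
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row {dup!r}")
    return df.astype(float)


def read_homolog_map(path: str | Path) -> pd.Series:
    """Two-column TSV source → target symbol map."""
    df = pd.read_csv(Path(path), sep="\t")
    src = df.iloc[:, 0].astype(str).str.upper()
    tgt = df.iloc[:, 1].astype(str).str.upper()
    if src.duplicated().any():
        raise ValueError(f"{path}: duplicate source symbols")
    return pd.Series(tgt.to_numpy(), index=pd.Index(src, name="source"),
                     name="target")


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GMT annotation file → ({set name: members}, {set name: description})."""
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT needs >=3 fields")
            name = fields[0]
            sets[name] = {g.upper() for g in fields[2:] if g}
            desc[name] = fields[1]
    return sets, desc


# ---------------------------------------------------------------------------
# synthetic bundle round trip

def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> Path:
    """Write one synthetic dataset as the standard TSV/JSON bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    region = bundle.config.region
    nx.write_edgelist(bundle.ppi, out / "ppi_edges.tsv", delimiter="\t",
                      data=False)
    for gwas, name in ((bundle.gwas_discovery, "gwas_discovery.tsv"),
                       (bundle.gwas_validation, "gwas_validation.tsv")):
        pd.DataFrame({"gene": gwas.p.index, "p": gwas.p.to_numpy()}).to_csv(
            out / name, sep="\t", index=False
        )
    for panel in (bundle.expr_ctrl, bundle.expr_trt):
        panel.values.to_csv(
            out / f"expression_{panel.condition}_{region}.tsv", sep="\t",
            index_label="gene",
        )
    for df, cond in ((bundle.probe_rma_ctrl, "control"),
                     (bundle.probe_rma_trt, "treatment")):
        df.to_csv(out / f"probe_rma_{cond}_{region}.tsv", sep="\t",
                  index_label="probeset")
    bundle.sscores.values.to_csv(out / f"sscores_{region}.tsv", sep="\t",
                                 index_label="probeset")
    pd.DataFrame({"probeset": bundle.probe_map.index,
                  "gene": bundle.probe_map.to_numpy()}).to_csv(
        out / "probe_map.tsv", sep="\t", index=False)
    pd.DataFrame({"source": bundle.homolog_map.index,
                  "target": bundle.homolog_map.to_numpy()}).to_csv(
        out / "homolog_map.tsv", sep="\t", index=False)
    truth = {
        "planted_genes": sorted(bundle.truth.planted_genes),
        "seed": bundle.truth.seed,
        "config": {k: getattr(bundle.config, k)
                   for k in bundle.config.__dataclass_fields__},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return out


def read_bundle(indir: str | Path) -> SyntheticBundle:
    """Read back a bundle written by :func:`write_bundle`."""
    ind = Path(indir)
    truth_doc = json.loads((ind / "truth.json").read_text())
    config = SyntheticConfig(**truth_doc["config"])
    truth = SyntheticTruth(frozenset(truth_doc["planted_genes"]), config,
                           truth_doc["seed"])
    region = config.region
    ppi = read_edge_list(ind / "ppi_edges.tsv")
    gwas_disc = read_gwas_table(ind / "gwas_discovery.tsv", study="discovery")
    gwas_val = read_gwas_table(ind / "gwas_validation.tsv", study="validation")
    expr = {}
    for cond in ("control", "treatment"):
        expr[cond] = ExpressionPanel(
            region, cond, read_matrix(ind / f"expression_{cond}_{region}.tsv")
        )
    # probeset ids are platform identifiers, not gene symbols: keep case
    probe_ctrl = read_matrix(ind / f"probe_rma_control_{region}.tsv",
                             uppercase_index=False)
    probe_trt = read_matrix(ind / f"probe_rma_treatment_{region}.tsv",
                            uppercase_index=False)
    sscores = SScorePanel(region, read_matrix(ind / f"sscores_{region}.tsv",
                                              uppercase_index=False))
    pm = pd.read_csv(ind / "probe_map.tsv", sep="\t")
    probe_map = pd.Series(
        pm["gene"].astype(str).str.upper().to_numpy(),
        index=pd.Index(pm["probeset"].astype(str), name="probeset"),
        name="gene",
    )
    homolog = read_homolog_map(ind / "homolog_map.tsv")
    return SyntheticBundle(
        config, truth, ppi, gwas_disc, gwas_val, expr["control"],
        expr["treatment"], sscores, probe_map, homolog, probe_ctrl, probe_trt,
    )


# ---------------------------------------------------------------------------
# result tables

def write_modules_table(modules, path: str | Path) -> None:
    """Per-module TSV: seed, genes, k, m, S_m, S_n, p, q."""
    rows = [{
        "seed": mo.seed_gene,
        "genes": ";".join(sorted(mo.genes)),
        "k": mo.k, "m": mo.m,
        "s_m": mo.s_m, "s_n": mo.s_n, "p": mo.p, "q": mo.q,
    } for mo in modules]
    pd.DataFrame(rows, columns=["seed", "genes", "k", "m", "s_m", "s_n",
                                "p", "q"]).to_csv(path, sep="\t", index=False)


def write_megamodule_table(
    mms, path: str | Path,
    gwas_node: GwasGeneStats | None = None,
    gwas_validation: GwasGeneStats | None = None,
) -> None:
    """Mega-module TSV with per-gene GWAS p-values, centralities and hubs."""
    rows = []
    for mm in mms:
        for g in sorted(mm.genes):
            rows.append({
                "megamodule": mm.name,
                "gene": g,
                "k_g": mm.k,
                "mm_s_n": mm.s_n,
                "mm_p": mm.p,
                "mm_q": mm.q,
                "p_discovery": (float(gwas_node.p[g])
                                if gwas_node is not None
                                and g in gwas_node.p.index else None),
                "p_validation": (float(gwas_validation.p[g])
                                 if gwas_validation is not None
                                 and g in gwas_validation.p.index else None),
                "connectivity": mm.connectivity.get(g),
                "eigencentrality": mm.eigencentrality.get(g),
                "hub": g in mm.hubs,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_graphml(genes, edges, path: str | Path) -> None:
    """GraphML export of one (mega-)module's induced subgraph."""
    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edges_from(edges)
    nx.write_graphml(g, path)
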