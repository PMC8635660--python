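"""Readers and writers for the pipeline's plain-text formats.

Tables are tab-separated with a header row; gene lists are one symbol per
line; networks export to SIF and GraphML (with a ``kind`` node attribute);
gene-set annotations use GMT.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .catalog import CompoundRecord, PPIEdge, normalize_symbol
from .network import PharmNetwork
from .topology import NodeTopologyProfile
from .transcriptome import ExpressionMatrix

log = logging.getLogger(__name__)


# -- compound catalog -------------------------------------------------------

def read_compound_catalog(path) -> list[CompoundRecord]:
    """Catalog TSV (compound_id, name, herb, ob, dl); one row per herb of origin.

    Rows for the same compound are aggregated into one record with the herb
    set unioned; rows with unparsable OB/DL are rejected with a logged error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"compound_id", "name", "herb", "ob", "dl"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing catalog columns {sorted(missing)}")
    records: dict[str, dict] = {}
    for i, row in df.iterrows():
        try:
            ob, dl = float(row["ob"]), float(row["dl"])
        except (TypeError, ValueError):
            log.error("%s row %d: non-numeric OB/DL (%r, %r) — rejected",
                      path, i, row["ob"], row["dl"])
            continue
        rec = records.setdefault(row["compound_id"], {
            "name": row["name"], "herbs": set(), "ob": ob, "dl": dl})
        rec["herbs"].add(row["herb"])
    return [
        CompoundRecord(compound_id=cid, name=r["name"],
                       herbs=frozenset(r["herbs"]), ob=r["ob"], dl=r["dl"])
        for cid, r in records.items()
    ]


def write_compound_catalog(records: Iterable[CompoundRecord], path) -> None:
    rows = [
        {"compound_id": r.compound_id, "name": r.name, "herb": h,
         "ob": f"{r.ob:.4f}", "dl": f"{r.dl:.4f}"}
        for r in records for h in sorted(r.herbs)
    ]
    pd.DataFrame(rows, columns=["compound_id", "name", "herb", "ob", "dl"]) \
        .to_csv(path, sep="\t", index=False)


# -- edge tables ------------------------------------------------------------

def read_edge_table(path) -> list[tuple[str, str]]:
    """Two-id-column TSV; extra columns ignored."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge table needs at least two columns")
    return [tuple(r) for r in df.iloc[:, :2].itertuples(index=False, name=None)]


def write_edge_table(edges: Iterable[tuple[str, str]], path,
                     columns: tuple[str, str] = ("source", "target")) -> None:
    pd.DataFrame(list(edges), columns=list(columns)).to_csv(path, sep="\t", index=False)


def read_ppi_table(path) -> list[PPIEdge]:
    """STRING-style TSV: protein_a, protein_b, combined_score (score in [0,1])."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: PPI table needs protein_a, protein_b, combined_score")
    edges = []
    seen: set[frozenset] = set()
    for a, b, s in df.iloc[:, :3].itertuples(index=False, name=None):
        a, b = normalize_symbol(str(a)), normalize_symbol(str(b))
        pair = frozenset((a, b))
        if pair in seen:
            continue
        seen.add(pair)
        edges.append(PPIEdge(a, b, float(s)))
    return edges


def write_ppi_table(edges: Iterable[PPIEdge], path) -> None:
    rows = [{"protein_a": e.protein_a, "protein_b": e.protein_b,
             "combined_score": f"{e.score:.3f}"} for e in edges]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"]) \
        .to_csv(path, sep="\t", index=False)


# -- gene lists and gene sets ----------------------------------------------

def read_gene_list(path) -> set[str]:
    out = set()
    for line in Path(path).read_text().splitlines():
        sym = normalize_symbol(line)
        if sym:
            out.add(sym)
    return out


def write_gene_list(symbols: Iterable[str], path) -> None:
    Path(path).write_text("\n".join(sorted(symbols)) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            continue
        sets[parts[0]] = {normalize_symbol(g) for g in parts[2:] if g.strip()}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path,
              description: str = "netpharm") -> None:
    lines = [
        "\t".join([name, description, *sorted(set(members))])
        for name, members in sorted(sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- expression -------------------------------------------------------------

def read_expression(matrix_path, groups_path) -> ExpressionMatrix:
    """Genes x samples TSV plus a two-column (sample, group) assignment TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
    if gdf.shape[1] < 2:
        raise ValueError(f"{groups_path}: group file needs sample and group columns")
    groups = pd.Series(gdf.iloc[:, 1].values, index=gdf.iloc[:, 0].values)
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(matrix: ExpressionMatrix, matrix_path, groups_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene",
                         float_format="%.6f")
    pd.DataFrame({"sample": matrix.groups.index, "group": matrix.groups.values}) \
        .to_csv(groups_path, sep="\t", index=False)


# -- networks ---------------------------------------------------------------

_SIF_INTERACTION = {
    frozenset(("herb", "compound")): "contains",
    frozenset(("compound", "target")): "targets",
    frozenset(("target",)): "interacts",
    frozenset(("target", "pathway")): "member_of",
}


def write_sif(net: PharmNetwork, path) -> None:
    """SIF export (nodeA <tab> interaction <tab> nodeB); isolated nodes as bare ids."""
    lines = []
    for u, v in sorted(map(lambda e: tuple(sorted(e)), net.graph.edges())):
        kinds = frozenset((net.kind_of(u), net.kind_of(v)))
        lines.append(f"{u}\t{_SIF_INTERACTION[kinds]}\t{v}")
    lines.extend(sorted(net.isolated_nodes))
    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(net: PharmNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def read_graphml(path) -> PharmNetwork:
    g = nx.read_graphml(path)
    net = PharmNetwork()
    for n, d in g.nodes(data=True):
        net.add_node(n, d["kind"])
    for u, v in g.edges():
        net.add_edge(u, v)
    return net


# -- profiles, indicators, reports -----------------------------------------

def write_profiles(profiles: Iterable[NodeTopologyProfile], path) -> None:
    pd.DataFrame([p.__dict__ for p in profiles]).to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_ranking(table: pd.DataFrame, path) -> None:
    """Ranking TSV with "+"-joined combination members."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10f")
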