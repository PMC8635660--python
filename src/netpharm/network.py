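"""The typed multilayer pharmacology network.

Nodes carry a ``kind`` attribute (herb, compound, target or pathway); edges
are undirected, simple (no self-loops, no duplicates) and typed by the kinds
of their endpoints.  Only four layer pairings are legal: herb–compound,
compound–target, target–target and target–pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

log = logging.getLogger(__name__)

NODE_KINDS = ("herb", "compound", "target", "pathway")

_ALLOWED_EDGE_KINDS = {
    frozenset(("herb", "compound")),
    frozenset(("compound", "target")),
    frozenset(("target",)),
    frozenset(("target", "pathway")),
}


class NetworkValidationError(ValueError):
    """Raised when an input row violates the typed-network invariants."""


@dataclass
class PharmNetwork:
    """Undirected typed multilayer graph of herbs, compounds, targets, pathways.

    Thin wrapper around a :class:`networkx.Graph` whose nodes carry a
    ``kind`` attribute.  The wrapper enforces the layer typing rules on
    mutation and exposes layer-aware convenience accessors.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    # -- construction -------------------------------------------------------
    def add_node(self, node_id: str, kind: str, **attrs) -> None:
        if kind not in NODE_KINDS:
            raise NetworkValidationError(f"unknown node kind {kind!r} for node {node_id!r}")
        existing = self.graph.nodes.get(node_id)
        if existing is not None and existing.get("kind") != kind:
            raise NetworkValidationError(
                f"node {node_id!r} declared both as {existing.get('kind')!r} and {kind!r}"
            )
        self.graph.add_node(node_id, kind=kind, **attrs)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise NetworkValidationError(f"self-loop on node {u!r}")
        for n in (u, v):
            if n not in self.graph:
                raise NetworkValidationError(f"edge endpoint {n!r} not declared as a node")
        kinds = frozenset((self.graph.nodes[u]["kind"], self.graph.nodes[v]["kind"]))
        if kinds not in _ALLOWED_EDGE_KINDS:
            raise NetworkValidationError(
                f"illegal edge between kinds {sorted(kinds)} ({u!r} – {v!r})"
            )
        self.graph.add_edge(u, v)

    # -- accessors ----------------------------------------------------------
    def nodes_of_kind(self, kind: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == kind]

    @property
    def herbs(self) -> list[str]:
        return self.nodes_of_kind("herb")

    @property
    def compounds(self) -> list[str]:
        return self.nodes_of_kind("compound")

    @property
    def targets(self) -> list[str]:
        return self.nodes_of_kind("target")

    @property
    def isolated_nodes(self) -> list[str]:
        return [n for n in self.graph if self.graph.degree(n) == 0]

    def targets_of_compound(self, compound_id: str) -> set[str]:
        """Target proteins adjacent to one compound node."""
        if compound_id not in self.graph:
            raise KeyError(f"compound {compound_id!r} not in network")
        return {
            n for n in self.graph.neighbors(compound_id)
            if self.graph.nodes[n]["kind"] == "target"
        }

    def kind_of(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["kind"]

    def subgraph(self, nodes: Iterable[str]) -> "PharmNetwork":
        return PharmNetwork(self.graph.subgraph(list(nodes)).copy())

    def copy(self) -> "PharmNetwork":
        return PharmNetwork(self.graph.copy())

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.graph

    def __iter__(self) -> Iterator[str]:
        return iter(self.graph)

    def validate(self) -> None:
        """Recheck all invariants; raises NetworkValidationError on violation."""
        for u, v in self.graph.edges():
            if u == v:
                raise NetworkValidationError(f"self-loop on {u!r}")
            kinds = frozenset((self.graph.nodes[u]["kind"], self.graph.nodes[v]["kind"]))
            if kinds not in _ALLOWED_EDGE_KINDS:
                raise NetworkValidationError(f"illegal edge {u!r} – {v!r} of kinds {sorted(kinds)}")
        for n, d in self.graph.nodes(data=True):
            if d.get("kind") not in NODE_KINDS:
                raise NetworkValidationError(f"node {n!r} has unknown kind {d.get('kind')!r}")


def build_pharm_network(
    herb_compound_edges: Iterable[tuple[str, str]],
    compound_target_edges: Iterable[tuple[str, str]],
    target_target_edges: Iterable[tuple[str, str]] = (),
    target_pathway_edges: Iterable[tuple[str, str]] = (),
    extra_nodes: Iterable[tuple[str, str]] = (),
) -> PharmNetwork:
    """Assemble the typed network from per-layer edge tables.

    Node kinds are inferred from the column a node appears in; a node that
    appears in incompatible columns raises :class:`NetworkValidationError`
    naming the offending row.  Self-loops and duplicate edges are dropped
    with a counted warning (the network is a simple graph).  ``extra_nodes``
    are (id, kind) pairs for nodes with no edges; they are retained and
    reported by :attr:`PharmNetwork.isolated_nodes`.
    """
    net = PharmNetwork()
    n_selfloops = 0
    n_duplicates = 0

    for node_id, kind in extra_nodes:
        net.add_node(node_id, kind)

    layers = (
        (herb_compound_edges, "herb", "compound"),
        (compound_target_edges, "compound", "target"),
        (target_target_edges, "target", "target"),
        (target_pathway_edges, "target", "pathway"),
    )
    for rows, kind_u, kind_v in layers:
        for row in rows:
            u, v = row[0], row[1]
            if u == v:
                n_selfloops += 1
                continue
            try:
                net.add_node(u, kind_u)
                net.add_node(v, kind_v)
            except NetworkValidationError as exc:
                raise NetworkValidationError(f"row ({u!r}, {v!r}): {exc}") from None
            if net.graph.has_edge(u, v):
                n_duplicates += 1
                continue
            net.add_edge(u, v)

    if n_selfloops:
        log.warning("build_pharm_network: dropped %d self-loop rows", n_selfloops)
    if n_duplicates:
        log.warning("build_pharm_network: collapsed %d duplicate edges", n_duplicates)
    return net
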