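"""Topological parameters and network-level stability indicators.

Per-node parameters (degree, betweenness, closeness, clustering coefficient,
topological coefficient) gate core-network extraction; the four network-level
indicators summarise the stability of a (possibly knocked-out) network:

* NC  — network centralization, (n/(n-2)) * (d_max/(n-1) - density), in [0, 1].
  1 for a star, 0 for any regular graph.
* CPL — characteristic path length: mean shortest-path length over unordered
  *connected* node pairs; disconnected pairs are excluded from the average
  rather than imputed a penalty distance.
* NH  — network heterogeneity: coefficient of variation of the degree
  sequence, sqrt(population variance) / mean.  0 iff all degrees equal.
* R   — robustness after a knockout: C / (N - Nr), the fraction of surviving
  nodes contained in the largest connected component (C = size of the largest
  surviving component, N = original node count, Nr = removed count).
  R = 1 iff the survivors are connected.

Conventions follow the ones common in network-pharmacology tooling:
betweenness is normalized by (n-1)(n-2)/2, closeness is computed within each
connected component (no harmonic variant, no whole-graph rescaling), and the
topological coefficient of a node n with k_n >= 2 neighbours is the mean of
J(n, m) / k_n over all nodes m that share at least one neighbour with n,
where J counts shared neighbours plus 1 if m is adjacent to n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .network import PharmNetwork


@dataclass(frozen=True)
class NodeTopologyProfile:
    node_id: str
    degree: int
    betweenness: float
    closeness: float
    clustering_coefficient: float
    topological_coefficient: float


@dataclass(frozen=True)
class StabilityIndicators:
    """The (NC, CPL, NH, R) 4-tuple for one network state."""

    nc: float
    cpl: float
    nh: float
    r: float

    def as_dict(self) -> dict[str, float]:
        return {"nc": self.nc, "cpl": self.cpl, "nh": self.nh, "r": self.r}


def _as_graph(net: PharmNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, PharmNetwork) else net


def topological_coefficient(g: nx.Graph, node) -> float:
    """Shared-neighbour topological coefficient; 0 for nodes with < 2 neighbours."""
    nbrs = set(g.neighbors(node))
    k = len(nbrs)
    if k < 2:
        return 0.0
    ratios = []
    for m in g:
        if m == node:
            continue
        shared = len(nbrs & set(g.neighbors(m)))
        if shared == 0:
            continue
        j = shared + (1 if g.has_edge(node, m) else 0)
        ratios.append(j / k)
    return float(np.mean(ratios)) if ratios else 0.0


def node_topology_profiles(net: PharmNetwork | nx.Graph) -> list[NodeTopologyProfile]:
    """One profile per node; isolated nodes get 0 for every parameter."""
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no topology profiles")
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    clustering = nx.clustering(g)
    return [
        NodeTopologyProfile(
            node_id=n,
            degree=g.degree(n),
            betweenness=float(betweenness[n]),
            closeness=float(closeness[n]),
            clustering_coefficient=float(clustering[n]),
            topological_coefficient=topological_coefficient(g, n),
        )
        for n in g
    ]


def network_centralization(net: PharmNetwork | nx.Graph) -> float:
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError(f"network centralization needs >= 3 nodes, got {n}")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    density = 2.0 * g.number_of_edges() / (n * (n - 1))
    return float((n / (n - 2.0)) * (degrees.max() / (n - 1.0) - density))


def characteristic_path_length(net: PharmNetwork | nx.Graph) -> float:
    """Mean shortest-path length over unordered connected node pairs."""
    g = _as_graph(net)
    if g.number_of_edges() == 0:
        raise ValueError("characteristic path length undefined for an edgeless graph")
    total = 0
    n_pairs = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                n_pairs += 1
    # each unordered pair counted twice; the ratio is unaffected
    return total / n_pairs


def network_heterogeneity(net: PharmNetwork | nx.Graph) -> float:
    g = _as_graph(net)
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    if degrees.size == 0 or degrees.mean() == 0:
        raise ValueError("network heterogeneity undefined when mean degree is 0")
    return float(np.sqrt(degrees.var()) / degrees.mean())


def robustness(
    net_after_knockout: PharmNetwork | nx.Graph,
    n_original: int,
    n_removed: int,
) -> float:
    """Largest-component fraction C/(N - Nr) of the surviving graph."""
    g = _as_graph(net_after_knockout)
    if n_removed >= n_original:
        raise ValueError("n_removed must be smaller than n_original")
    if g.number_of_nodes() == 0:
        raise ValueError("robustness undefined for an empty surviving graph")
    if g.number_of_nodes() != n_original - n_removed:
        raise ValueError(
            f"surviving graph has {g.number_of_nodes()} nodes, "
            f"expected N - Nr = {n_original - n_removed}"
        )
    c = max(len(cc) for cc in nx.connected_components(g))
    return c / (n_original - n_removed)


def stability_indicators(
    net_after_knockout: PharmNetwork | nx.Graph,
    n_original: int | None = None,
    n_removed: int = 0,
) -> StabilityIndicators:
    """All four indicators for one (possibly knocked-out) network state."""
    g = _as_graph(net_after_knockout)
    if n_original is None:
        n_original = g.number_of_nodes() + n_removed
    return StabilityIndicators(
        nc=network_centralization(g),
        cpl=characteristic_path_length(g),
        nh=network_heterogeneity(g),
        r=robustness(g, n_original, n_removed),
    )


_GATING_DEFAULT = ("degree", "betweenness", "closeness")


def extract_core_network(
    net: PharmNetwork,
    profiles: Iterable[NodeTopologyProfile] | None = None,
    gating: tuple[str, ...] = _GATING_DEFAULT,
    strict: bool = True,
) -> PharmNetwork:
    """Median-rule core extraction.

    Retains nodes whose gating parameters (default: degree, betweenness,
    closeness) all exceed the network-wide medians — strictly by default —
    and returns the induced subgraph.  Clustering and topological
    coefficients are computed and may be added to ``gating`` but do not gate
    by default: on sparse multilayer networks their medians are typically 0
    and gating on them empties the core.
    """
    if profiles is None:
        profiles = node_topology_profiles(net)
    profiles = list(profiles)
    ids = {p.node_id for p in profiles}
    if ids != set(net.graph.nodes):
        raise ValueError("profiles must cover exactly the network's nodes")
    valid = {"degree", "betweenness", "closeness",
             "clustering_coefficient", "topological_coefficient"}
    unknown = set(gating) - valid
    if unknown:
        raise ValueError(f"unknown gating parameters: {sorted(unknown)}")

    medians = {p_name: float(np.median([getattr(p, p_name) for p in profiles]))
               for p_name in gating}
    if strict:
        keep = [p.node_id for p in profiles
                if all(getattr(p, g) > medians[g] for g in gating)]
    else:
        keep = [p.node_id for p in profiles
                if all(getattr(p, g) >= medians[g] for g in gating)]
    if not keep:
        raise ValueError(
            "core extraction removed every node; relax the gating rule "
            "(fewer parameters or strict=False)"
        )
    return net.subgraph(keep)
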