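import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from netpharm.network import PharmNetwork, build_pharm_network
from netpharm.synthetic import ExpressionDesign, SynthConfig, synth_pharm_network


@pytest.fixture
def toy_network() -> PharmNetwork:
    """2 herbs, 3 compounds, 4 targets, 8 edges."""
    return build_pharm_network(
        herb_compound_edges=[("h1", "c1"), ("h1", "c2"), ("h2", "c3")],
        compound_target_edges=[("c1", "t1"), ("c2", "t2"), ("c3", "t3"), ("c3", "t4")],
        target_target_edges=[("t1", "t2"), ("t2", "t3")],
    )


@pytest.fixture
def small_synth():
    """Small deterministic tripartite network with one planted hub compound."""
    cfg = SynthConfig(
        n_herbs=3, n_compounds=8, n_targets=60, n_decoy_compounds=4,
        targets_per_compound=(2, 5), n_planted_hubs=1, planted_hub_boost=5.0,
        expr_design=ExpressionDesign(n_genes=120, n_per_group=4, n_deg=30),
        seed=11,
    )
    net, planted = synth_pharm_network(cfg)
    return cfg, net, planted


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    return nx.gnp_random_graph(n, p, seed=seed)


def as_pharm(g: nx.Graph) -> PharmNetwork:
    """Wrap an arbitrary simple graph as a target-layer network."""
    net = PharmNetwork()
    for n in g.nodes:
        net.add_node(str(n), "target")
    for u, v in g.edges:
        net.add_edge(str(u), str(v))
    return net
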