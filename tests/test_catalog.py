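"""Compound screening, PPI expansion, gene-set intersection and network build."""

import types

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netpharm.catalog import (
    CompoundRecord,
    PPIEdge,
    expand_targets_ppi,
    filter_compounds_admet,
    intersect_target_sets,
    venn_regions,
)
from netpharm.network import NetworkValidationError, build_pharm_network

from oracles import adjacency


def record(cid="c", ob=50.0, dl=0.5, herbs=("h1",)):
    return CompoundRecord(compound_id=cid, name=cid, herbs=frozenset(herbs),
                          ob=ob, dl=dl)


class TestAdmetFilter:
    def test_thresholds_are_inclusive(self):
        assert filter_compounds_admet([record(ob=30.0, dl=0.18)], 30, 0.18)

    @pytest.mark.parametrize("ob,dl", [(29.999, 0.18), (30.0, 0.1799)])
    def test_just_below_either_threshold_fails(self, ob, dl):
        assert filter_compounds_admet([record(ob=ob, dl=dl)], 30, 0.18) == []

    def test_empty_catalog(self):
        assert filter_compounds_admet([], 30, 0.18) == []

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(42)
        catalog = [record(f"c{i}", ob=rng.uniform(0, 100), dl=rng.uniform(0, 1))
                   for i in range(20)]
        got = filter_compounds_admet(catalog, 30, 0.18)
        expected = [r for r in catalog if r.ob >= 30 and r.dl >= 0.18]
        assert got == expected  # order preserved too

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        catalog = [record(f"c{i}", ob=rng.uniform(0, 100), dl=rng.uniform(0, 1))
                   for i in range(30)]
        once = filter_compounds_admet(catalog, 30, 0.18)
        assert filter_compounds_admet(once, 30, 0.18) == once

    def test_invalid_record_rejected_not_raised(self, caplog):
        bad = types.SimpleNamespace(compound_id="bad", ob=float("nan"), dl=0.5)
        with caplog.at_level("ERROR"):
            assert filter_compounds_admet([bad], 30, 0.18) == []
        assert "bad" in caplog.text


class TestPPIExpansion:
    def test_boundary_score_is_excluded(self):
        edges = [PPIEdge("A", "B", 0.850)]
        assert expand_targets_ppi({"A"}, edges, 0.850) == {"A"}

    def test_above_boundary_included(self):
        edges = [PPIEdge("A", "B", 0.851)]
        assert expand_targets_ppi({"A"}, edges, 0.850) == {"A", "B"}

    def test_empty_ppi_is_identity(self):
        assert expand_targets_ppi({"A", "B"}, [], 0.5) == {"A", "B"}

    def test_single_round_no_transitive_closure(self):
        edges = [PPIEdge("A", "B", 0.9), PPIEdge("B", "C", 0.9)]
        assert expand_targets_ppi({"A"}, edges, 0.85) == {"A", "B"}

    def test_matches_brute_force_neighbourhood(self):
        rng = np.random.default_rng(3)
        nodes = [f"N{i}" for i in range(15)]
        edges = []
        for i in range(15):
            for j in range(i + 1, 15):
                if rng.random() < 0.3:
                    edges.append(PPIEdge(nodes[i], nodes[j], float(rng.random())))
        seeds = {"N0", "N5", "N9"}
        score_min = 0.5
        kept = [(e.protein_a, e.protein_b) for e in edges if e.score > score_min]
        adj = adjacency(nodes, kept)
        expected = set(seeds) | {v for s in seeds for v in adj[s]}
        assert expand_targets_ppi(seeds, edges, score_min) == expected

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_superset_and_monotone_in_score_min(self, s1, s2):
        rng = np.random.default_rng(17)
        nodes = [f"N{i}" for i in range(10)]
        edges = [PPIEdge(nodes[i], nodes[j], float(rng.random()))
                 for i in range(10) for j in range(i + 1, 10) if rng.random() < 0.4]
        seeds = {"N0", "N3"}
        lo, hi = sorted((s1, s2))
        big = expand_targets_ppi(seeds, edges, lo)
        small = expand_targets_ppi(seeds, edges, hi)
        assert seeds <= small <= big


class TestIntersection:
    def test_forced_example(self):
        got = intersect_target_sets({"x": {"A", "B", "C"}, "y": {"B", "C"}, "z": {"B"}})
        assert got == {"B"}

    def test_disjoint_sets(self):
        assert intersect_target_sets({"x": {"A"}, "y": {"B"}}) == set()

    def test_case_and_whitespace_normalized(self):
        assert intersect_target_sets({"x": {" tp53 "}, "y": {"TP53"}}) == {"TP53"}

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            intersect_target_sets({"only": {"A"}})

    def test_matches_exhaustive_membership_oracle(self):
        rng = np.random.default_rng(5)
        universe = [f"G{i}" for i in range(200)]
        sets = {name: {universe[i] for i in rng.choice(200, 50, replace=False)}
                for name in ("a", "b", "c")}
        got = intersect_target_sets(sets)
        expected = {g for g in universe if all(g in s for s in sets.values())}
        assert got == expected

    def test_commutative_and_result_subset_of_inputs(self):
        rng = np.random.default_rng(9)
        universe = [f"G{i}" for i in range(60)]
        sets = {n: {universe[i] for i in rng.choice(60, 25, replace=False)}
                for n in ("a", "b", "c")}
        reordered = {k: sets[k] for k in ("c", "a", "b")}
        got = intersect_target_sets(sets)
        assert got == intersect_target_sets(reordered)
        assert all(got <= s for s in sets.values())

    def test_venn_region_counts_partition_the_union(self):
        sets = {"a": {"1", "2", "3"}, "b": {"2", "3", "4"}, "c": {"3", "5"}}
        regions = venn_regions(sets)
        assert regions["a&b&c"] == 1          # {3}
        assert regions["a&b"] == 1            # {2}
        assert regions["a"] == 1 and regions["c"] == 1
        assert sum(regions.values()) == len(set().union(*sets.values()))


class TestNetworkBuild:
    def test_direct_construction(self, toy_network):
        assert len(toy_network) == 9
        assert toy_network.graph.number_of_edges() == 9  # 3 hc + 4 ct + 2 tt
        assert len(toy_network.compounds) == 3

    def test_duplicate_edge_collapsed(self):
        net = build_pharm_network([("h", "c")], [("c", "t"), ("c", "t")])
        assert net.graph.number_of_edges() == 2

    def test_self_loop_dropped(self):
        net = build_pharm_network([("h", "c")], [("c", "c"), ("c", "t")])
        assert not any(u == v for u, v in net.graph.edges())

    def test_conflicting_kind_raises_with_row(self):
        with pytest.raises(NetworkValidationError, match="h1"):
            build_pharm_network([("h1", "c1")], [("c1", "h1")])

    def test_isolated_nodes_retained_and_flagged(self):
        net = build_pharm_network([("h", "c")], [], extra_nodes=[("t_alone", "target")])
        assert "t_alone" in net
        assert net.isolated_nodes == ["t_alone"]

    def test_random_tripartite_reparse(self, small_synth):
        _, net, _ = small_synth
        net.validate()
        # independent reconstruction from the edge lists must agree
        hc = [(u, v) if net.kind_of(u) == "herb" else (v, u)
              for u, v in net.graph.edges()
              if {net.kind_of(u), net.kind_of(v)} == {"herb", "compound"}]
        ct = [(u, v) if net.kind_of(u) == "compound" else (v, u)
              for u, v in net.graph.edges()
              if {net.kind_of(u), net.kind_of(v)} == {"compound", "target"}]
        tt = [(u, v) for u, v in net.graph.edges()
              if {net.kind_of(u), net.kind_of(v)} == {"target"}]
        rebuilt = build_pharm_network(hc, ct, tt)
        assert set(rebuilt.graph.nodes) == set(net.graph.nodes)
        assert {frozenset(e) for e in rebuilt.graph.edges()} == \
               {frozenset(e) for e in net.graph.edges()}
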