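"""Induced network-module extraction, z-scores, display attributes, export."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from glyconet import (
    annotate_and_export,
    candidate_zscores,
    induce_module,
    load_exported,
    load_network,
    neighborhood_connectivity,
)
from glyconet.simulate import simulate_network


def brute_force_z(net, seeds, v):
    """Recompute the binomial z for one candidate from adjacency lists."""
    present = set(seeds) & set(net.nodes)
    N, n = net.number_of_nodes(), len(present)
    d = len(list(net.neighbors(v)))
    q = d / (N - 1)
    o = len(set(net.neighbors(v)) & present)
    if q >= 1:
        return math.inf if o == n else -math.inf
    return (o - n * q) / math.sqrt(n * q * (1 - q))


class TestLoadNetwork:
    def test_triangle_edge_list(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text("a\tb\tppi\nb\tc\tppi\na\tc\tppi\n")
        g = load_network(f)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_sif_column_order(self, tmp_path):
        f = tmp_path / "net.sif"
        f.write_text("a\tppi\tb\n")
        g = load_network(f)
        assert g.has_edge("a", "b")

    def test_self_loop_dropped(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text("a\ta\tppi\na\tb\tppi\n")
        g = load_network(f)
        assert not g.has_edge("a", "a") and g.has_edge("a", "b")

    def test_duplicate_edges_collapse(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text("a\tb\tppi\nb\ta\tppi\n")
        assert load_network(f).number_of_edges() == 1

    def test_unknown_edge_type_rejected(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text("a\tb\tteleport\n")
        with pytest.raises(ValueError, match="unknown edge type"):
            load_network(f)

    def test_malformed_line_reports_number(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text("a\tb\tppi\na\tb\n")
        with pytest.raises(ValueError, match="line 2"):
            load_network(f)


class TestCandidateZscores:
    def _star_net(self):
        # v adjacent to exactly the 3 seeds; 10 nodes total
        g = nx.Graph()
        g.add_nodes_from([f"x{i}" for i in range(6)])
        g.add_edges_from([("v", "s1"), ("v", "s2"), ("v", "s3")])
        return g

    def test_hand_computed_z(self):
        g = self._star_net()
        z = candidate_zscores(g, ["s1", "s2", "s3"])
        assert z["v"] == pytest.approx((3 - 1) / math.sqrt(2 / 3), rel=1e-9)

    def test_null_expectation_is_zero(self):
        # o = n*q exactly: n=3 seeds, N=10, d(v)=3, o=1 -> need q=1/3, o=1
        g = nx.Graph()
        g.add_nodes_from([f"x{i}" for i in range(6)])
        g.add_nodes_from(["s2", "s3"])
        g.add_edges_from([("v", "s1"), ("v", "x0"), ("v", "x1")])
        assert g.number_of_nodes() == 10
        z = candidate_zscores(g, ["s1", "s2", "s3"])
        assert z["v"] == pytest.approx(0.0, abs=1e-12)

    def test_z_increases_with_seed_adjacency(self):
        zs = []
        for o in (1, 2, 3):
            g = nx.Graph()
            g.add_nodes_from([f"x{i}" for i in range(6)])
            for i in range(1, o + 1):
                g.add_edge("v", f"s{i}")
            for i in range(o, 3):  # keep d(v)=3 with non-seed fillers
                g.add_edge("v", f"x{i}")
            zs.append(candidate_zscores(g, ["s1", "s2", "s3"])["v"])
        assert zs[0] < zs[1] < zs[2]

    def test_no_seed_present_is_error(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError, match="no seed present"):
            candidate_zscores(g, ["nope"])

    def test_missing_seeds_reported_not_fatal(self):
        g = nx.Graph([("s1", "v")])
        z = candidate_zscores(g, ["s1", "ghost"])
        assert z.attrs["missing_seeds"] == ["ghost"]

    def test_agrees_with_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(8, 30))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            seeds = [f"n{i}" for i in rng.choice(n, size=4, replace=False)]
            try:
                z = candidate_zscores(g, seeds)
            except ValueError:
                continue
            for v in z.index:
                assert z[v] == pytest.approx(brute_force_z(g, seeds, v), rel=1e-12)


class TestInduceModule:
    def _triangle_net(self):
        g = nx.Graph()
        g.add_nodes_from([f"x{i}" for i in range(7)])
        g.add_edge("a", "b", edge_type="protein-protein")
        g.add_edge("a", "c", edge_type="protein-protein")
        g.add_edge("b", "c", edge_type="biochemical")
        return g

    def test_hand_computed_triangle_inclusion(self):
        # c adjacent to both seeds in a 10-node net, d(c)=2 -> z ~ 2.645
        g = self._triangle_net()
        z = candidate_zscores(g, ["a", "b"])
        expect = (2 - 4 / 9) / math.sqrt(2 * (2 / 9) * (7 / 9))
        assert z["c"] == pytest.approx(expect, rel=1e-9)
        mod = induce_module(g, ["a", "b"], z_threshold=2.0)
        assert set(mod.nodes) == {"a", "b", "c"}
        assert mod.nodes["c"]["role"] == "connector"

    def test_high_threshold_keeps_seed_subgraph(self):
        g = self._triangle_net()
        mod = induce_module(g, ["a", "b"], z_threshold=1e9)
        assert set(mod.nodes) == {"a", "b"}
        assert mod.has_edge("a", "b")

    def test_minus_inf_threshold_adds_all_neighbors(self):
        g = self._triangle_net()
        mod = induce_module(g, ["a", "b"], z_threshold=-math.inf)
        assert set(mod.nodes) == {"a", "b", "c"}

    def test_monotone_shrinkage_in_threshold(self):
        net, seeds, _ = simulate_network(seed=5)
        prev = None
        for zt in (-5.0, 0.0, 2.0, 5.0, 20.0):
            nodes = set(induce_module(net, seeds, zt).nodes)
            if prev is not None:
                assert nodes <= prev
            prev = nodes

    def test_module_edges_subset_of_source(self):
        net, seeds, _ = simulate_network(seed=6)
        mod = induce_module(net, seeds, 2.0)
        assert set(map(frozenset, mod.edges)) <= set(map(frozenset, net.edges))
        assert set(seeds) <= set(mod.nodes)


class TestNeighborhoodConnectivity:
    def test_path_graph_hand_values(self):
        g = nx.path_graph(["a", "b", "c"])
        nc = neighborhood_connectivity(g)
        assert nc["b"] == 1.0 and nc["a"] == 2.0 and nc["c"] == 2.0

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_node("solo")
        assert neighborhood_connectivity(g)["solo"] == 0.0

    def test_complete_graph_symmetry(self):
        g = nx.complete_graph(4)
        assert (neighborhood_connectivity(g) == 3.0).all()


class TestExportRoundTrip:
    def _annotated_module(self):
        g = self_net = nx.Graph()
        g.add_edge("a", "b", edge_type="protein-protein")
        g.add_edge("b", "c", edge_type="biochemical")
        g.add_edge("a", "c", edge_type="gene-regulatory")
        mod = induce_module(g, ["a", "b"], z_threshold=-10)
        degs = pd.DataFrame(
            {"direction": ["up", "down"], "selected": [True, True]},
            index=pd.Index(["a", "b"], name="gene"),
        )
        return mod, degs

    @pytest.mark.parametrize("fmt", ["graphml", "xgmml"])
    def test_round_trip_preserves_graph_and_attributes(self, tmp_path, fmt):
        mod, degs = self._annotated_module()
        path = tmp_path / f"m.{fmt}"
        annotate_and_export(mod, degs, path, fmt=fmt)
        back = load_exported(path)
        assert set(back.nodes) == set(mod.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, mod.edges))
        assert back.nodes["a"]["expression_state"] == "up"
        assert back.nodes["b"]["expression_state"] == "down"
        assert back.nodes["c"]["expression_state"] == "absent"
        assert back.nodes["c"]["role"] == "connector"
        assert back.edges["b", "c"]["edge_type"] == "biochemical"
        nc = neighborhood_connectivity(mod)
        assert back.nodes["a"]["neighborhood_connectivity"] == pytest.approx(nc["a"])

    def test_empty_module_is_valid_file(self, tmp_path):
        mod = nx.Graph()
        path = tmp_path / "empty.xgmml"
        annotate_and_export(mod, None, path, fmt="xgmml")
        assert load_exported(path).number_of_nodes() == 0

    def test_export_is_byte_stable(self, tmp_path):
        mod, degs = self._annotated_module()
        p1, p2 = tmp_path / "m1.graphml", tmp_path / "m2.graphml"
        annotate_and_export(mod, degs, p1, fmt="graphml")
        annotate_and_export(mod, degs, p2, fmt="graphml")
        assert p1.read_bytes() == p2.read_bytes()


class TestPlantedConnector:
    def test_planted_connector_tops_candidates(self):
        hits = 0
        for seed in range(100):
            net, seeds, truth = simulate_network(seed=seed)
            z = candidate_zscores(net, seeds)
            if z.idxmax() == truth.planted_connector_ids[0]:
                hits += 1
        assert hits >= 95
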