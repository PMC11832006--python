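"""Subnetwork statistics, controllability, centralities, TF-target network."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mrpipe.data_io import RegulonSet, SignedNetwork, StateMatrix
from mrpipe.network_analysis import (
    build_tf_target_network,
    centralities,
    induce_mr_subnetwork,
    mds_drivers,
    random_subnetwork_null,
)

from conftest import random_signed_network


def brute_force_min_drivers(network: SignedNetwork) -> int:
    """Exhaustive maximum matching over all subsets of distinct arcs."""
    arcs = sorted({(u, v) for u, v, _ in network.edges})
    best = 0
    for size in range(len(arcs), 0, -1):
        if size <= best:
            break
        for subset in combinations(arcs, size):
            sources = {u for u, _ in subset}
            targets = {v for _, v in subset}
            if len(sources) == size and len(targets) == size:
                best = size
                break
        if best == size:
            break
    return max(1, len(network.nodes) - best)


class TestInduceSubnetwork:
    def test_disconnected_selection(self):
        net = SignedNetwork(edges=[("A", "B", 1), ("B", "C", 1)])
        sub, stats = induce_mr_subnetwork(net, ["A", "C"])
        assert sub.n_edges == 0
        assert stats.n_connected_in_lcc == 1

    def test_full_selection_returns_whole_network(self, chain_network):
        sub, stats = induce_mr_subnetwork(chain_network, ["A", "B", "C"])
        assert sub.n_edges == chain_network.n_edges
        assert stats.n_connected_in_lcc == 3

    def test_triangle_partial_induction(self):
        net = SignedNetwork(edges=[("A", "B", 1), ("B", "C", 1), ("C", "A", -1)])
        sub, stats = induce_mr_subnetwork(net, ["A", "B"])
        assert sub.n_edges == 1
        assert stats.n_connected_in_lcc == 2


class TestRandomSubnetworkNull:
    def test_full_k_reproduces_graph(self, chain_network):
        summary = random_subnetwork_null(chain_network, 3, n_draws=10, seed=0)
        assert summary["lcc_size_median"] == 3
        assert summary["edge_count_median"] == 2

    def test_edgeless_graph(self):
        net = SignedNetwork(edges=[], nodes={"A", "B", "C", "D"})
        summary = random_subnetwork_null(net, 2, n_draws=20, seed=1)
        assert summary["lcc_size_max"] == 1
        assert summary["edge_count_max"] == 0

    def test_deterministic_under_seed(self, default_config):
        from mrpipe.synthetic import generate_network_and_regulons

        net, _, _ = generate_network_and_regulons(default_config)
        a = random_subnetwork_null(net, 10, n_draws=50, seed=3)
        b = random_subnetwork_null(net, 10, n_draws=50, seed=3)
        assert a == b

    def test_planted_dense_module_beats_null(self):
        rng = np.random.default_rng(11)
        # sparse background of 40 nodes + a dense 8-node module
        edges = []
        nodes = [f"n{i}" for i in range(40)]
        for _ in range(20):
            u, v = rng.choice(40, size=2, replace=False)
            edges.append((nodes[u], nodes[v], 1))
        module = nodes[:8]
        for u in module:
            for v in module:
                if u != v:
                    edges.append((u, v, 1))
        net = SignedNetwork(edges=list(set(edges)), nodes=set(nodes))
        _, stats = induce_mr_subnetwork(net, module)
        null = random_subnetwork_null(net, 8, n_draws=200, seed=5)
        assert stats.n_connected_in_lcc >= null["lcc_size_max"]


class TestMdsDrivers:
    def test_directed_path_has_one_driver(self):
        net = SignedNetwork(edges=[("A", "B", 1), ("B", "C", 1)])
        result = mds_drivers(net)
        assert result.n_drivers == 1
        assert result.witness_driver_set == ["A"]

    def test_isolated_nodes_all_drivers(self):
        net = SignedNetwork(edges=[], nodes={"A", "B", "C", "D"})
        result = mds_drivers(net)
        assert result.n_drivers == 4
        assert result.witness_driver_set == ["A", "B", "C", "D"]

    def test_out_star_drivers(self):
        net = SignedNetwork(edges=[("hub", "l1", 1), ("hub", "l2", 1), ("hub", "l3", 1)])
        result = mds_drivers(net)
        assert result.matching_size == 1
        assert result.n_drivers == 3

    def test_cycle_needs_one_driver(self):
        net = SignedNetwork(edges=[("A", "B", 1), ("B", "C", 1), ("C", "A", 1)])
        result = mds_drivers(net)
        assert result.matching_size == 3
        assert result.n_drivers == 1  # perfect matching floor

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            mds_drivers(SignedNetwork(edges=[], nodes=set()))

    def test_matches_exhaustive_search_on_small_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(60):
            n_nodes = int(rng.integers(2, 9))
            net = random_signed_network(rng, n_nodes, int(rng.integers(1, 2 * n_nodes + 1)))
            result = mds_drivers(net)
            assert result.n_drivers == brute_force_min_drivers(net)
            assert len(result.witness_driver_set) == result.n_drivers

    def test_witness_set_covers_unmatched_inputs(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            net = random_signed_network(rng, 7, 12)
            result = mds_drivers(net)
            arcs = sorted({(u, v) for u, v, _ in net.edges})
            g = nx.Graph()
            out_nodes = [("out", u) for u in sorted(net.nodes)]
            g.add_nodes_from(out_nodes, bipartite=0)
            g.add_nodes_from(("in", v) for v in sorted(net.nodes))
            g.add_edges_from((("out", u), ("in", v)) for u, v in arcs)
            matching = nx.bipartite.hopcroft_karp_matching(g, top_nodes=out_nodes)
            unmatched = {v for v in net.nodes if ("in", v) not in matching}
            assert unmatched <= set(result.witness_driver_set)


class TestCentralities:
    def test_path_closed_form(self):
        net = SignedNetwork(edges=[("A", "B", 1), ("B", "C", 1)])
        records = {r.node: r for r in centralities(net)}
        assert [records[n].outdegree for n in "ABC"] == [1, 1, 0]
        assert records["A"].closeness == pytest.approx(1 / 3)
        assert records["C"].closeness == 0.0

    def test_complete_digraph_closed_form(self):
        nodes = list("ABCD")
        edges = [(u, v, 1) for u in nodes for v in nodes if u != v]
        records = centralities(SignedNetwork(edges=edges))
        assert all(r.closeness == pytest.approx(1 / 3) for r in records)

    def test_parallel_opposite_edges_count_once_in_outdegree(self):
        net = SignedNetwork(edges=[("A", "B", 1), ("A", "B", -1)])
        records = {r.node: r for r in centralities(net)}
        assert records["A"].outdegree == 1

    def test_matches_brute_force_shortest_paths(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            net = random_signed_network(rng, int(rng.integers(3, 21)), int(rng.integers(5, 40)))
            g = net.to_networkx()
            dist = dict(nx.all_pairs_shortest_path_length(g))
            for record in centralities(net):
                total = sum(d for v, d in dist[record.node].items() if v != record.node)
                expected = 1.0 / total if total > 0 else 0.0
                assert record.closeness == pytest.approx(expected)


class TestTfTargetNetwork:
    def build(self, state_row, deg_rows, mode, **kwargs):
        samples = [f"s{i}" for i in range(len(state_row))]
        tf_states = StateMatrix(
            values=pd.DataFrame([state_row], index=["TF1"], columns=samples), tag="TF"
        )
        deg = pd.DataFrame(deg_rows, index=samples).T
        regulons = RegulonSet(regulons={"TF1": {g: mode for g in deg.index}})
        return build_tf_target_network(tf_states, deg, regulons, seed=3, **kwargs)

    def test_concordant_stimulation_included(self):
        state = [1, 1, -1, 0, 1, -1, 1, 0, -1, 1] * 3
        deg = {"g1": state}
        edges, outdeg = self.build(state, deg, mode=1)
        assert bool(edges.loc[0, "included"])
        assert outdeg.loc[0, "outdegree_all"] == 1

    def test_anticorrelated_stimulation_excluded(self):
        state = [1, 1, -1, 0, 1, -1, 1, 0, -1, 1] * 3
        deg = {"g1": [-s for s in state]}
        edges, _ = self.build(state, deg, mode=1)
        assert not bool(edges.loc[0, "included"])

    def test_concordant_repression_included(self):
        state = [1, 1, -1, 0, 1, -1, 1, 0, -1, 1] * 3
        deg = {"g1": [-s for s in state]}
        edges, _ = self.build(state, deg, mode=-1)
        assert bool(edges.loc[0, "included"])

    def test_mr_restricted_outdegree(self):
        state = [1, 1, -1, 0, 1, -1, 1, 0, -1, 1] * 3
        deg = {"g1": state, "g2": state}
        edges, outdeg = self.build(state, deg, mode=1, mr_genes=["g2"])
        assert outdeg.loc[0, "outdegree_all"] == 2
        assert outdeg.loc[0, "outdegree_mr"] == 1
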