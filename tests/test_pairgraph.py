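"""Pair graph construction, Aho graph, feedback-arc repair, peeling heights."""

import random

import networkx as nx
import pytest

from helpers import cyclic_core, exact_mfas_size
from netcombin import (
    ValidationError,
    aho_graph,
    build_pair_graph,
    extract_triplets,
    height_from_dag,
    is_dag,
    longest_path_length,
    make_dag,
    parse_triplets,
    simulate_network,
    simulate_tree,
    triplets_of_tree,
)


class TestBuildPairGraph:
    def test_caterpillar_tau_structure(self, chain_tau):
        g = build_pair_graph(chain_tau)
        assert g.number_of_nodes() == 6  # C(4,2), isolated pairs retained
        expected = {
            (("c", "d"), ("b", "c")), (("c", "d"), ("b", "d")),
            (("c", "d"), ("a", "c")), (("c", "d"), ("a", "d")),
            (("b", "d"), ("a", "b")), (("b", "d"), ("a", "d")),
            (("b", "c"), ("a", "b")), (("b", "c"), ("a", "c")),
        }
        assert set(g.edges()) == expected

    def test_cyclic_tau_has_cycle(self, cyclic_tau):
        assert not is_dag(build_pair_graph(cyclic_tau))

    def test_single_triplet_arcs(self):
        g = build_pair_graph(parse_triplets("i j k\n"))
        assert set(g.edges()) == {
            (("i", "j"), ("i", "k")),
            (("i", "j"), ("j", "k")),
        }


class TestAhoGraph:
    def test_components_on_full_taxon_set(self, six_taxon_tau):
        g = aho_graph(six_taxon_tau, six_taxon_tau.leaf_set())
        comps = sorted(map(sorted, nx.connected_components(g)))
        assert comps == [["a", "b", "c", "d"], ["e", "f"]]

    def test_stuck_component_stays_connected(self, cyclic_tau):
        g = aho_graph(cyclic_tau, {"b", "c", "d"})
        assert nx.is_connected(g)

    def test_no_internal_triplets_gives_isolated_nodes(self, chain_tau):
        g = aho_graph(chain_tau, {"a", "b"})
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 2


class TestMakeDag:
    def test_repairs_cyclic_tau_with_single_arc(self, cyclic_tau):
        g = build_pair_graph(cyclic_tau)
        repaired, removed = make_dag(g)
        assert is_dag(repaired)
        assert removed == {(("c", "d"), ("b", "c"))}

    def test_acyclic_input_untouched(self, chain_tau):
        g = build_pair_graph(chain_tau)
        repaired, removed = make_dag(g)
        assert removed == set()
        assert set(repaired.edges()) == set(g.edges())

    def test_three_cycle_repair_is_optimal(self):
        g = nx.DiGraph([("u", "v"), ("v", "w"), ("w", "u")])
        repaired, removed = make_dag(g)
        assert is_dag(repaired)
        assert len(removed) == exact_mfas_size(g) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_removal_count_at_least_mfas_optimum(self, seed):
        net = simulate_network(5, 2, seed)
        tau = extract_triplets(net, 1.0, seed)
        g = build_pair_graph(tau)
        _, removed = make_dag(g)
        if cyclic_core(g).number_of_edges() <= 10:  # keep the oracle exhaustive
            assert len(removed) >= exact_mfas_size(g)
        else:
            assert len(removed) >= 1 and not is_dag(g)

    def test_always_acyclic_on_random_inputs(self):
        rng = random.Random(7)
        for _ in range(200):
            n = rng.randint(4, 8)
            k = rng.randint(0, 2)
            tau = extract_triplets(
                simulate_network(n, k, rng), rng.uniform(0.3, 1.0), rng
            )
            if len(tau.leaf_set()) < 3:
                continue
            repaired, _ = make_dag(build_pair_graph(tau))
            assert is_dag(repaired)

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_consistent_tau_needs_no_repair(self, seed):
        tau = triplets_of_tree(simulate_tree(7, seed))
        g = build_pair_graph(tau)
        assert is_dag(g)
        _, removed = make_dag(g)
        assert removed == set()


class TestLongestPath:
    def test_caterpillar_tau(self, chain_tau):
        assert longest_path_length(build_pair_graph(chain_tau)) == 2

    def test_repaired_cyclic_tau(self, cyclic_tau):
        repaired, _ = make_dag(build_pair_graph(cyclic_tau))
        assert longest_path_length(repaired) == 3

    def test_trivial_graphs(self):
        g = nx.DiGraph()
        g.add_node(("a", "b"))
        assert longest_path_length(g) == 0
        with pytest.raises(ValidationError):
            longest_path_length(nx.DiGraph([("u", "v"), ("v", "u")]))


class TestHeightFromDag:
    def test_caterpillar_tau_heights(self, chain_tau):
        h = height_from_dag(build_pair_graph(chain_tau))
        assert h.get("a", "b") == h.get("a", "c") == h.get("a", "d") == 3
        assert h.get("b", "c") == h.get("b", "d") == 2
        assert h.get("c", "d") == 1

    def test_repaired_cyclic_tau_heights(self, cyclic_tau):
        repaired, _ = make_dag(build_pair_graph(cyclic_tau))
        h = height_from_dag(repaired)
        assert h.get("a", "b") == h.get("a", "c") == h.get("a", "d") == 4
        assert h.get("b", "d") == 3
        assert h.get("c", "d") == 2
        assert h.get("b", "c") == 1

    def test_arcless_graph_all_ones(self):
        g = nx.DiGraph()
        g.add_nodes_from([("a", "b"), ("a", "c"), ("b", "c")])
        h = height_from_dag(g)
        assert set(h.values.values()) == {1}

    @pytest.mark.parametrize("seed", range(5))
    def test_arc_monotonicity(self, seed):
        """For every arc u -> v of the repaired graph, value(u) < value(v)."""
        net = simulate_network(6, 1, seed)
        tau = extract_triplets(net, 1.0, seed)
        repaired, _ = make_dag(build_pair_graph(tau))
        h = height_from_dag(repaired)
        for u, v in repaired.edges():
            assert h.values[u] < h.values[v]

    def test_cyclic_input_rejected(self):
        with pytest.raises(ValidationError):
            height_from_dag(nx.DiGraph([("u", "v"), ("v", "u")]))
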