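"""Network model, exact consistency, heights, statistics and eNewick."""

import random
from itertools import combinations

import networkx as nx
import pytest

from helpers import brute_network_consistent
from netcombin import (
    RootedNetwork,
    RootedTree,
    Triplet,
    ValidationError,
    consistent_triplet_set,
    extract_triplets,
    is_consistent_network,
    is_consistent_tree,
    level,
    network_height,
    parse_enewick,
    reticulation_count,
    simulate_network,
    write_enewick,
)


class TestModel:
    def test_two_roots_rejected(self):
        g = nx.DiGraph([("r1", "a"), ("r1", "b"), ("r2", "b"), ("r2", "c")])
        with pytest.raises(ValidationError):
            RootedNetwork(g)

    def test_bad_degree_rejected(self):
        # root with out-degree 3
        g = nx.DiGraph([("r", "a"), ("r", "b"), ("r", "c")])
        with pytest.raises(ValidationError):
            RootedNetwork(g)

    def test_cycle_rejected(self):
        g = nx.DiGraph([("r", "a"), ("r", "u"), ("u", "v"), ("v", "u")])
        with pytest.raises(ValidationError):
            RootedNetwork(g)

    def test_tree_round_trip(self):
        t = RootedTree.from_newick("((a,b),(c,d));")
        net = RootedNetwork.from_tree(t)
        assert reticulation_count(net) == 0
        assert net.to_tree() == t


class TestConsistency:
    def test_galled_examples(self, galled_network):
        assert is_consistent_network(Triplet("b", "c", "d"), galled_network)
        assert is_consistent_network(Triplet("c", "d", "b"), galled_network)
        assert not is_consistent_network(Triplet("b", "d", "c"), galled_network)

    def test_displays_its_defining_triplets(self, galled_network, cyclic_tau):
        assert len(consistent_triplet_set(galled_network, cyclic_tau)) == len(cyclic_tau)

    def test_missing_label_rejected(self, galled_network):
        with pytest.raises(ValidationError):
            is_consistent_network(Triplet("a", "b", "z"), galled_network)

    @pytest.mark.parametrize("seed", range(4))
    def test_tree_shaped_network_reduces_to_tree_consistency(self, seed):
        net = simulate_network(6, 0, seed)
        tree = net.to_tree()
        leaves = sorted(tree.leaf_set())
        for x, y, z in combinations(leaves, 3):
            for t in (Triplet(x, y, z), Triplet(x, z, y), Triplet(y, z, x)):
                assert is_consistent_network(t, net) == is_consistent_tree(t, tree)

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force_oracle(self, seed):
        net = simulate_network(5, 1, seed)
        leaves = net.leaves()
        for x, y, z in combinations(leaves, 3):
            for t in (Triplet(x, y, z), Triplet(x, z, y), Triplet(y, z, x)):
                assert is_consistent_network(t, net) == brute_network_consistent(
                    net.graph, t.i, t.j, t.k
                )


class TestNetworkHeight:
    def test_galled_heights(self, galled_network):
        h = network_height(galled_network)
        assert h.length == 4
        assert h.get("a", "b") == h.get("a", "c") == h.get("a", "d") == 4
        assert h.get("b", "d") == 3
        assert h.get("b", "c") == 2 and h.get("c", "d") == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_tree_shaped_equals_tree_height(self, seed):
        from netcombin import tree_height

        net = simulate_network(6, 0, seed)
        tree = net.to_tree()
        assert dict(network_height(net).values) == dict(tree_height(tree).values)

    @pytest.mark.parametrize("seed", range(10))
    def test_height_sufficiency_never_contradicts_exact_check(self, seed):
        """h_N(i,j) < h_N(i,k) or < h_N(j,k) implies real consistency."""
        rng = random.Random(seed)
        net = simulate_network(rng.randint(4, 7), rng.randint(0, 2), rng)
        h = network_height(net)
        leaves = net.leaves()
        for x, y, z in combinations(leaves, 3):
            for t in (Triplet(x, y, z), Triplet(x, z, y), Triplet(y, z, x)):
                hij = h.get(t.i, t.j)
                if hij < h.get(t.i, t.k) or hij < h.get(t.j, t.k):
                    assert is_consistent_network(t, net)


class TestStatistics:
    def test_galled_stats(self, galled_network):
        assert reticulation_count(galled_network) == 1
        assert level(galled_network) == 1

    def test_binary_tree_stats(self):
        net = RootedNetwork.from_tree(RootedTree.from_newick("((a,b),(c,d));"))
        assert reticulation_count(net) == 0 and level(net) == 0

    def test_two_independent_galls_are_level_one(self):
        """Two reticulations in separate biconnected components."""
        g = nx.DiGraph(
            [
                ("r", "s1"), ("r", "s2"),
                ("s1", "x1"), ("s1", "y1"), ("x1", "a"), ("x1", "h1"),
                ("y1", "b"), ("y1", "h1"), ("h1", "c"),
                ("s2", "x2"), ("s2", "y2"), ("x2", "d"), ("x2", "h2"),
                ("y2", "e"), ("y2", "h2"), ("h2", "f"),
            ]
        )
        net = RootedNetwork(g)
        assert reticulation_count(net) == 2
        assert level(net) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_level_bounded_by_reticulations(self, seed):
        net = simulate_network(7, 2, seed)
        assert level(net) <= reticulation_count(net) == 2


class TestENewick:
    def test_round_trip_preserves_structure(self, galled_network):
        text = write_enewick(galled_network)
        assert "#H1" in text
        back = parse_enewick(text)
        assert reticulation_count(back) == 1 and level(back) == 1
        assert back.leaf_set() == galled_network.leaf_set()
        assert write_enewick(back) == text

    @pytest.mark.parametrize("seed", range(6))
    def test_round_trip_preserves_displayed_triplets(self, seed):
        net = simulate_network(6, 2, seed)
        back = parse_enewick(write_enewick(net))
        assert set(extract_triplets(net, 1.0)) == set(extract_triplets(back, 1.0))

    def test_plain_newick_parses_as_tree_network(self):
        net = parse_enewick("((a,b),(c,d));")
        assert reticulation_count(net) == 0

    def test_malformed_input_rejected(self):
        for bad in ["((a,b)", "(a,b));", "(a,(b,));"]:
            with pytest.raises(ValidationError):
                parse_enewick(bad)
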