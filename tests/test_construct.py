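"""Edge-pair valuation, augmentation, candidate selection, full pipeline."""

import networkx as nx
import pytest

from netcombin import (
    BuildHalt,
    RootedNetwork,
    RootedTree,
    ValidationError,
    augment,
    build,
    consistent_triplet_set,
    level,
    netcombin_run,
    pair_value,
    parse_triplets,
    reticulation_count,
    select_best,
    simulate_network,
    simulate_tree,
    extract_triplets,
    triplets_of_tree,
    write_enewick,
)

ELEVEN = (
    "i j k\ni j l\ni j m\nl m k\nl m j\nl m i\nm k i\nm k j\nl k i\nl k j\nl k m\n"
)


class TestPairValue:
    def test_some_pair_fixes_the_missing_triplet(self):
        tree = RootedTree.from_newick("((i,j),(k,(l,m)));")
        net = RootedNetwork.from_tree(tree)
        tau_rem = parse_triplets("l k m\n")
        values = []
        edges = sorted(net.graph.edges(), key=lambda e: (str(e[0]), str(e[1])))
        for e in edges:
            for f in edges:
                if e == f:
                    continue
                v = pair_value(net, e, f, tau_rem)
                if v is not None:
                    values.append(v)
        assert max(values) == 1

    def test_cycle_creating_pair_is_infeasible(self):
        net = RootedNetwork.from_tree(RootedTree.from_newick("((a,b),(c,d));"))
        # e below f's head: the new arc would close a directed cycle
        (root,) = [n for n, d in net.graph.in_degree() if d == 0]
        x = next(s for s in net.graph.successors(root) if "a" in nx.descendants(net.graph, s))
        assert pair_value(net, (x, "a"), (root, x), parse_triplets("a b c\n")) is None

    def test_empty_remainder_values_zero(self):
        net = RootedNetwork.from_tree(RootedTree.from_newick("((a,b),(c,d));"))
        edges = sorted(net.graph.edges(), key=lambda e: (str(e[0]), str(e[1])))
        from netcombin import TripletSet

        v = pair_value(net, edges[0], edges[-1], TripletSet(()))
        assert v in (0, None)

    def test_bad_edges_rejected(self):
        net = RootedNetwork.from_tree(RootedTree.from_newick("((a,b),(c,d));"))
        edges = list(net.graph.edges())
        with pytest.raises(ValidationError):
            pair_value(net, edges[0], edges[0], parse_triplets("a b c\n"))
        with pytest.raises(ValidationError):
            pair_value(net, ("x", "y"), edges[0], parse_triplets("a b c\n"))


class TestAugment:
    def test_consistent_input_adds_nothing(self):
        tree = simulate_tree(6, 3)
        net = augment(tree, triplets_of_tree(tree))
        assert reticulation_count(net) == 0
        assert net.to_tree() == tree

    def test_eleven_triplet_example_needs_one_edge(self):
        tree = RootedTree.from_newick("((i,j),(k,(l,m)));")
        tau = parse_triplets(ELEVEN)
        net = augment(tree, tau)
        assert reticulation_count(net) == 1
        assert len(consistent_triplet_set(net, tau)) == len(tau)

    @pytest.mark.parametrize("seed", range(3))
    def test_level_one_extraction_fully_recovered(self, seed):
        source = simulate_network(6, 1, seed)
        tau = extract_triplets(source, 1.0, seed)
        from netcombin import build_candidate_trees, binarize

        t_bin = binarize(build_candidate_trees(tau)[0], tau, "m2")
        net = augment(t_bin, tau)
        assert len(consistent_triplet_set(net, tau)) == len(tau)

    def test_leafset_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            augment(RootedTree.from_newick("(a,b);"), parse_triplets("a b c\n"))


class TestSelectBest:
    def test_fewest_reticulations_wins(self, galled_network):
        tree_net = RootedNetwork.from_tree(RootedTree.from_newick("((a,b),(c,d));"))
        assert select_best([galled_network, tree_net]) is tree_net

    def test_tie_broken_by_list_order(self, galled_network):
        other = galled_network.copy()
        assert select_best([galled_network, other]) is galled_network

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            select_best([])


class TestPipeline:
    def test_single_triplet_gives_tree(self):
        net, report = netcombin_run(parse_triplets("i j k\n"))
        assert reticulation_count(net) == 0
        assert net.to_tree() == RootedTree.from_newick("(k,(i,j));")
        assert len(report.candidates) == 27

    def test_tree_consistent_tau_recovers_source(self):
        source = simulate_tree(8, 17)
        net, report = netcombin_run(triplets_of_tree(source))
        assert reticulation_count(net) == 0
        assert net.to_tree() == source
        assert report.removed_arcs == []

    def test_unresolvable_set_needs_a_reticulation(self, cyclic_tau):
        assert isinstance(build(cyclic_tau), BuildHalt)  # no tree exists
        net, _ = netcombin_run(cyclic_tau)
        assert len(consistent_triplet_set(net, cyclic_tau)) == len(cyclic_tau)
        assert reticulation_count(net) >= 1
        assert level(net) >= 1

    def test_deterministic_output(self, cyclic_tau):
        n1, _ = netcombin_run(cyclic_tau)
        n2, _ = netcombin_run(cyclic_tau)
        assert write_enewick(n1) == write_enewick(n2)

    def test_report_shape(self, cyclic_tau):
        _, report = netcombin_run(cyclic_tau)
        d = report.to_dict()
        assert len(d["candidates"]) == 27
        for cand in d["candidates"]:
            assert set(cand) == {
                "strategy",
                "measure",
                "reticulations",
                "level",
                "edges_added",
            }
        assert d["removed_arcs"] == [[["b", "c"], ["c", "d"]]] or d["removed_arcs"] == [
            [["c", "d"], ["b", "c"]]
        ]

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValidationError):
            netcombin_run(parse_triplets(""))
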