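"""Shared fixtures: small triplet sets and networks used across the suite."""

from __future__ import annotations

import networkx as nx
import pytest

from netcombin import RootedNetwork, RootedTree, parse_triplets


@pytest.fixture
def chain_tau():
    """Triplets of the caterpillar (a,(b,(c,d))): {cd|b, cd|a, bd|a, bc|a}."""
    return parse_triplets("c d b\nc d a\nb d a\nb c a\n")


@pytest.fixture
def cyclic_tau():
    """Five triplets on four taxa whose pair graph is cyclic; no tree displays them."""
    return parse_triplets("b c a\nb d a\nc d a\nb c d\nc d b\n")


@pytest.fixture
def six_taxon_tau():
    """Twenty triplets displayed by ((((c,d),b),a),(e,f))."""
    text = (
        "c d b\nc d a\nc d e\nc d f\n"
        "e f a\ne f b\ne f c\ne f d\n"
        "d b a\nd b e\nd b f\n"
        "d a e\nd a f\n"
        "c b a\nc b e\nc b f\n"
        "a b e\na b f\n"
        "a c e\na c f\n"
    )
    return parse_triplets(text)


@pytest.fixture
def dense_five_tau():
    """A dense triplet set on five taxa."""
    return parse_triplets(
        "a b c\na d b\nb e a\na c d\na e c\nd e a\nb d c\nb c e\nb e d\nd e c\n"
    )


@pytest.fixture
def galled_network():
    """The simplest (level-1) network displaying the cyclic five-triplet set.

    One reticulation h receives from both sides of the split below v and
    leads to leaf c.
    """
    g = nx.DiGraph(
        [
            ("r", "a"),
            ("r", "v"),
            ("v", "x"),
            ("v", "y"),
            ("x", "b"),
            ("x", "h"),
            ("y", "d"),
            ("y", "h"),
            ("h", "c"),
        ]
    )
    return RootedNetwork(g)


@pytest.fixture
def caterpillar_tree():
    return RootedTree.from_newick("(a,(b,(c,d)));")


@pytest.fixture
def balanced_five_tree():
    """The tree ((a,(b,c)),(d,e)) with longest path 3."""
    return RootedTree.from_newick("((a,(b,c)),(d,e));")
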