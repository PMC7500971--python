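"""Independent oracles and generators shared by the test modules.

These deliberately re-derive results by brute force or from alternative
characterizations (LCA comparison, exhaustive path enumeration, exhaustive
feedback-set search) so that agreement with the package is informative.
"""

from __future__ import annotations

import random
from itertools import combinations, product

import networkx as nx

from netcombin import RootedTree, Triplet, simulate_tree
from netcombin.trees import TreeNode


# -- LCA-based triplet consistency on trees (independent of heights) ---------

def lca_consistent(t: Triplet, tree: RootedTree) -> bool:
    """ij|k is consistent iff lca(i, j) is a strict descendant of lca(i, j, k)."""
    parent: dict[int, int | None] = {}
    leaf_node: dict[str, int] = {}
    counter = 0

    def walk(node: TreeNode, par: int | None) -> None:
        nonlocal counter
        me = counter
        counter += 1
        parent[me] = par
        if node.is_leaf:
            leaf_node[node.label] = me
        for child in node.children:
            walk(child, me)

    walk(tree.root, None)

    def ancestors(n: int) -> list[int]:
        chain = [n]
        while parent[chain[-1]] is not None:
            chain.append(parent[chain[-1]])
        return chain

    def lca(nodes: list[int]) -> int:
        chains = [ancestors(n) for n in nodes]
        common = set(chains[0]).intersection(*map(set, chains[1:]))
        return min(common, key=lambda c: -len(ancestors(c)))  # deepest common

    l_ij = lca([leaf_node[t.i], leaf_node[t.j]])
    l_ijk = lca([leaf_node[t.i], leaf_node[t.j], leaf_node[t.k]])
    return l_ij != l_ijk


# -- brute-force triplet consistency on networks -----------------------------

def brute_network_consistent(g: nx.DiGraph, i: str, j: str, k: str) -> bool:
    """Enumerate every 4-tuple of simple paths and test pairwise disjointness."""
    nodes = list(g.nodes())
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            p1s = list(nx.all_simple_paths(g, u, i))
            p2s = list(nx.all_simple_paths(g, u, j))
            p3s = list(nx.all_simple_paths(g, v, u))
            p4s = list(nx.all_simple_paths(g, v, k))
            for p1, p2, p3, p4 in product(p1s, p2s, p3s, p4s):
                s1, s2, s3, s4 = map(set, (p1, p2, p3, p4))
                if (
                    s1 & s2 == {u}
                    and s1 & s3 == {u}
                    and not s1 & s4
                    and s2 & s3 == {u}
                    and not s2 & s4
                    and s3 & s4 == {v}
                ):
                    return True
    return False


# -- exact minimum feedback arc set ------------------------------------------

def cyclic_core(g: nx.DiGraph) -> nx.DiGraph:
    """Drop every node outside all cycles (repeatedly strip degree-0 ends).

    Arcs outside the core lie on no directed cycle, so the minimum feedback
    arc set of the core equals that of the whole graph.
    """
    h = g.copy()
    while True:
        doomed = [n for n in h.nodes() if h.in_degree(n) == 0 or h.out_degree(n) == 0]
        if not doomed:
            return h
        h.remove_nodes_from(doomed)


def exact_mfas_size(g: nx.DiGraph) -> int:
    """Smallest number of arcs whose removal makes g acyclic (exhaustive).

    Only intended for graphs whose cyclic core is tiny.
    """
    core = cyclic_core(g)
    arcs = list(core.edges())
    for r in range(len(arcs) + 1):
        for combo in combinations(arcs, r):
            h = core.copy()
            h.remove_edges_from(combo)
            if nx.is_directed_acyclic_graph(h):
                return r
    raise AssertionError("unreachable")


# -- random non-binary trees -------------------------------------------------

def random_nonbinary_tree(n: int, rng: random.Random, p_contract: float = 0.4) -> RootedTree:
    """A random multifurcating tree: random binary shape with edges contracted."""
    tree = simulate_tree(n, rng)
    root = tree.root.copy()

    def contract(node: TreeNode) -> None:
        new_children: list[TreeNode] = []
        for child in node.children:
            contract(child)
            if not child.is_leaf and rng.random() < p_contract:
                new_children.extend(child.children)
            else:
                new_children.append(child)
        node.children = new_children

    contract(root)
    return RootedTree(root)
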