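"""Rooted phylogenetic networks: model, triplet consistency, heights, statistics.

A rooted network is a connected DAG whose nodes fall into four classes:
one root (in 0, out 2), tree nodes (in 1, out 2), reticulation nodes
(in 2, out 1) and labeled leaves (in 1, out 0).  Reticulations encode
non-treelike events (hybridization, recombination, lateral transfer); the
level of a network is the maximum number of reticulations in any
biconnected component of its underlying undirected graph, so a tree is
level-0 and a galled tree level-1.

A triplet ij|k is consistent with a network N when N contains distinct
nodes u, v and pairwise internally node-disjoint paths u->i, u->j, v->u
and v->k, i.e. the triplet embeds as a subdivision.  The decision here is
exact: candidate (u, v) pairs are pruned by ancestry and a backtracking
search certifies the four disjoint paths.
"""

from __future__ import annotations

import re
from itertools import count
from typing import Iterator

import networkx as nx

from .errors import ValidationError
from .heights import PairHeights, pair_key
from .trees import RootedTree, TreeNode
from .triplets import Triplet, TripletSet

__all__ = [
    "RootedNetwork",
    "is_consistent_network",
    "consistent_triplet_set",
    "network_height",
    "reticulation_count",
    "level",
    "write_enewick",
    "parse_enewick",
]


class RootedNetwork:
    """A rooted, leaf-labeled phylogenetic network over a ``networkx`` DiGraph.

    Leaf nodes are their taxon labels (strings); internal nodes are opaque
    hashable identifiers.  Binary rooted trees are the degenerate case with
    no reticulation nodes.
    """

    def __init__(self, graph: nx.DiGraph, validate: bool = True):
        self.graph = graph
        if validate:
            self.validate()
        self._root = next(n for n, d in graph.in_degree() if d == 0)
        self._maps: tuple[dict, dict] | None = None
        self._anc_cache: dict[object, frozenset] = {}

    # -- structure ------------------------------------------------------------
    @property
    def root(self):
        return self._root

    def leaves(self) -> list[str]:
        return sorted(n for n, d in self.graph.out_degree() if d == 0)

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaves())

    def reticulations(self) -> list:
        return [n for n, d in self.graph.in_degree() if d == 2]

    def validate(self) -> None:
        g = self.graph
        if g.number_of_nodes() == 0:
            raise ValidationError("empty network")
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("network must be acyclic")
        if not nx.is_weakly_connected(g):
            raise ValidationError("network must be connected")
        roots = [n for n, d in g.in_degree() if d == 0]
        if len(roots) != 1:
            raise ValidationError(f"network needs exactly one root, found {len(roots)}")
        for n in g.nodes():
            din, dout = g.in_degree(n), g.out_degree(n)
            ok = (
                (din == 0 and dout == 2)      # root
                or (din == 1 and dout == 2)   # tree node
                or (din == 2 and dout == 1)   # reticulation
                or (din == 1 and dout == 0)   # leaf
            )
            if not ok:
                raise ValidationError(
                    f"node {n!r} has degree (in={din}, out={dout}), not a valid class"
                )
        labels = [n for n, d in g.out_degree() if d == 0]
        if any(not isinstance(lab, str) or not lab for lab in labels):
            raise ValidationError("leaves must be labeled by non-empty strings")

    # -- cached ancestry ------------------------------------------------------
    def adjacency_maps(self) -> tuple[dict, dict]:
        """Cached (successor, predecessor) adjacency dicts with sorted neighbors."""
        if self._maps is None:
            self._maps = succ_pred_maps(self.graph)
        return self._maps

    def ancestors_of(self, node) -> frozenset:
        """All strict ancestors of ``node`` (cached per network)."""
        if node not in self._anc_cache:
            _, pred = self.adjacency_maps()
            self._anc_cache[node] = _ancestor_set(pred, node)
        return self._anc_cache[node]

    # -- construction ---------------------------------------------------------
    @classmethod
    def from_tree(cls, tree: RootedTree) -> "RootedNetwork":
        """Convert a binary rooted tree; internal nodes get fresh integer ids."""
        if not tree.is_binary():
            raise ValidationError("only binary trees are valid networks")
        g = nx.DiGraph()
        ids = count()

        def add(node: TreeNode):
            if node.is_leaf:
                g.add_node(node.label)
                return node.label
            me = next(ids)
            g.add_node(me)
            for child in node.children:
                g.add_edge(me, add(child))
            return me

        add(tree.root)
        if g.number_of_nodes() == 1:
            raise ValidationError("a single leaf is not a network")
        return cls(g)

    def to_tree(self) -> RootedTree:
        """Convert back to a tree; fails if the network has reticulations."""
        if self.reticulations():
            raise ValidationError("network with reticulations is not a tree")

        def grow(node) -> TreeNode:
            succ = sorted(self.graph.successors(node), key=str)
            if not succ:
                return TreeNode(node)
            return TreeNode(children=[grow(c) for c in succ])

        return RootedTree(grow(self._root))

    def copy(self) -> "RootedNetwork":
        return RootedNetwork(self.graph.copy(), validate=False)

    def __repr__(self) -> str:
        return (
            f"RootedNetwork(leaves={len(self.leaves())}, "
            f"reticulations={len(self.reticulations())})"
        )


# --------------------------------------------------------------------------
# Consistency
# --------------------------------------------------------------------------
# The embedding search runs on plain successor/predecessor dicts rather than
# the DiGraph so that the augmentation loop can evaluate thousands of
# tentative networks without building graph objects.

SuccMap = dict
PredMap = dict


def succ_pred_maps(g: nx.DiGraph) -> tuple[SuccMap, PredMap]:
    succ = {n: tuple(sorted(g.successors(n), key=str)) for n in g.nodes()}
    pred = {n: tuple(sorted(g.predecessors(n), key=str)) for n in g.nodes()}
    return succ, pred


def _ancestor_set(pred: PredMap, node) -> frozenset:
    """Strict ancestors via reverse BFS."""
    seen: set = set()
    frontier = list(pred[node])
    while frontier:
        x = frontier.pop()
        if x in seen:
            continue
        seen.add(x)
        frontier.extend(pred[x])
    return frozenset(seen)


def triplet_embeds(
    succ: SuccMap, pred: PredMap, i: str, j: str, k: str, anc_cache: dict | None = None
) -> bool:
    """Exact embedding decision on adjacency maps.

    Candidate u (common ancestor of the cherry) and v (ancestor of u and of
    the outgroup) pairs are enumerated, pruned by ancestry; for each, a
    backtracking search certifies pairwise internally node-disjoint paths
    v->u, u->i, u->j and v->k.
    """
    if anc_cache is None:
        anc_cache = {}

    def anc(node) -> frozenset:
        if node not in anc_cache:
            anc_cache[node] = _ancestor_set(pred, node)
        return anc_cache[node]

    anc_k = anc(k)
    for u in sorted(anc(i) & anc(j), key=str):
        for v in sorted(anc(u) & anc_k, key=str):
            if _four_disjoint_paths(succ, u, v, i, j, k):
                return True
    return False


def _four_disjoint_paths(succ: SuccMap, u, v, i: str, j: str, k: str) -> bool:
    """Backtracking search for the four pairwise internally disjoint paths.

    Sharing rules: the two paths from u share only u; the v->u path shares
    u with them and v with the v->k path; the v->k path is disjoint from
    the u-paths.  Leaves never occur as path interiors (out-degree 0), so
    the distinct endpoints i, j, k cannot collide.
    """
    for p3 in _simple_paths_avoiding(succ, v, u, frozenset((i, j, k))):
        used3 = frozenset(p3)  # includes v and u
        for p1 in _simple_paths_avoiding(succ, u, i, used3 - {u}):
            used1 = frozenset(p1)
            for p2 in _simple_paths_avoiding(succ, u, j, (used3 | used1) - {u}):
                used2 = frozenset(p2)
                forbidden = (used3 | used1 | used2) - {v}
                for _ in _simple_paths_avoiding(succ, v, k, forbidden):
                    return True
    return False


def _simple_paths_avoiding(
    succ: SuccMap, src, dst, forbidden: frozenset
) -> Iterator[list]:
    """DFS over simple src->dst paths avoiding ``forbidden`` nodes entirely."""
    if src in forbidden or dst in forbidden:
        return
    if src == dst:
        yield [src]
        return
    stack: list[tuple[object, list]] = [(src, [src])]
    while stack:
        node, path = stack.pop()
        for nxt in succ[node]:
            if nxt in forbidden or nxt in path:
                continue
            if nxt == dst:
                yield path + [nxt]
            else:
                stack.append((nxt, path + [nxt]))


def is_consistent_network(t: Triplet, net: RootedNetwork) -> bool:
    """Exact decision: does the triplet embed as a subdivision in the network?"""
    leaves = net.leaf_set()
    if not t.labels <= leaves:
        missing = sorted(t.labels - leaves)
        raise ValidationError(f"labels {missing} not in the network")
    succ, pred = net.adjacency_maps()
    return triplet_embeds(succ, pred, t.i, t.j, t.k, anc_cache=net._anc_cache)


def consistent_triplet_set(net: RootedNetwork, tau: TripletSet) -> TripletSet:
    """The subset of ``tau`` consistent with the network.

    The sufficient height-function condition is tried first (cheap, one
    height computation certifies most consistent triplets); only triplets
    it cannot certify go through the exact embedding search.
    """
    leaves = net.leaf_set()
    if len(leaves) < 2:
        return TripletSet((), universe=tau.universe)
    h = network_height(net)
    succ, pred = net.adjacency_maps()
    kept = []
    for t in tau:
        if not t.labels <= leaves:
            continue
        hij = h.get(t.i, t.j)
        if hij < h.get(t.i, t.k) or hij < h.get(t.j, t.k):
            kept.append(t)
        elif triplet_embeds(succ, pred, t.i, t.j, t.k, anc_cache=net._anc_cache):
            kept.append(t)
    return TripletSet(kept, universe=tau.universe)


# --------------------------------------------------------------------------
# Heights and statistics
# --------------------------------------------------------------------------

def network_height(net: RootedNetwork) -> PairHeights:
    """h_N(a, b) = min over lowest common ancestors c of l_N - d(r, c).

    Depths d(r, .) are LONGEST-path distances from the root, and C_ab is the
    set of common ancestors with no strictly lower common ancestor.  On a
    tree this reduces to the tree height function.
    """
    g = net.graph
    leaves = net.leaves()
    if len(leaves) < 2:
        raise ValidationError("height function needs at least 2 leaves")
    order = list(nx.topological_sort(g))
    depth: dict[object, int] = {}
    for n in order:
        preds = list(g.predecessors(n))
        depth[n] = 0 if not preds else max(depth[p] for p in preds) + 1
    l_n = max(depth.values())

    # descendant sets in reverse topological order
    desc: dict[object, frozenset] = {}
    for n in reversed(order):
        succ = list(g.successors(n))
        desc[n] = frozenset(succ).union(*(desc[c] for c in succ)) if succ else frozenset()

    anc = {leaf: net.ancestors_of(leaf) | {leaf} for leaf in leaves}
    values: dict[tuple[str, str], int] = {}
    for idx, a in enumerate(leaves):
        for b in leaves[idx + 1 :]:
            common = anc[a] & anc[b]
            lowest = [c for c in common if not (desc[c] & common)]
            values[pair_key(a, b)] = min(l_n - depth[c] for c in lowest)
    return PairHeights(values, l_n)


def reticulation_count(net: RootedNetwork) -> int:
    """Number of in-degree-2 nodes."""
    return len(net.reticulations())


def level(net: RootedNetwork) -> int:
    """Maximum reticulation count over biconnected components (0 for trees)."""
    rets = set(net.reticulations())
    if not rets:
        return 0
    undirected = net.graph.to_undirected(as_view=True)
    return max(
        len(rets & comp) for comp in nx.biconnected_components(undirected)
    )


# --------------------------------------------------------------------------
# Extended Newick I/O
# --------------------------------------------------------------------------

def write_enewick(net: RootedNetwork) -> str:
    """Canonical extended Newick: reticulations tagged #H1, #H2, ...

    Each reticulation is printed in full under its lexicographically first
    parent context and as a bare ``#Hn`` tag elsewhere; children everywhere
    are sorted by their smallest descendant leaf label, so equal networks
    produce byte-identical strings.
    """
    g = net.graph
    rets = sorted(net.reticulations(), key=lambda n: _min_leaf(g, n))
    tags = {n: f"#H{idx}" for idx, n in enumerate(rets, start=1)}
    expanded: set = set()

    def render(node) -> str:
        if node in tags:
            if node in expanded:
                return tags[node]
            expanded.add(node)
            inner = _render_children(node)
            return f"{inner}{tags[node]}"
        if g.out_degree(node) == 0:
            return node
        return _render_children(node)

    def _render_children(node) -> str:
        parts = sorted(
            (render(c) for c in g.successors(node)), key=_tag_sort_key
        )
        return "(" + ",".join(parts) + ")"

    def _tag_sort_key(s: str) -> str:
        labels = [x for x in re.split(r"[(),]", s) if x]
        return min(labels)

    return render(net.root) + ";"


def _min_leaf(g: nx.DiGraph, node) -> str:
    reach = nx.descendants(g, node) | {node}
    return min(n for n in reach if g.out_degree(n) == 0)


def parse_enewick(text: str) -> RootedNetwork:
    """Parse extended Newick with #Hn reticulation tags into a network."""
    s = text.strip()
    if s.endswith(";"):
        s = s[:-1]
    g = nx.DiGraph()
    ids = count()
    ret_nodes: dict[str, object] = {}
    pos = 0

    def node_for_tag(tag: str):
        if tag not in ret_nodes:
            ret_nodes[tag] = f"_{tag}_{next(ids)}"
        return ret_nodes[tag]

    def parse_node():
        nonlocal pos
        children = []
        if pos < len(s) and s[pos] == "(":
            pos += 1
            children.append(parse_node())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(parse_node())
            if pos >= len(s) or s[pos] != ")":
                raise ValidationError(f"unbalanced parentheses in eNewick: {text!r}")
            pos += 1
        label = _consume_label()
        m = re.fullmatch(r"([^#]*)#(H\d+)", label) if "#" in label else None
        if m:
            me = node_for_tag("#" + m.group(2))
        elif children:
            me = next(ids)
            g.add_node(me)
        else:
            if not label:
                raise ValidationError(f"empty leaf label in eNewick: {text!r}")
            me = label
            g.add_node(me)
        for child in children:
            g.add_edge(me, child)
        return me

    def _consume_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        label = s[start:pos]
        if pos < len(s) and s[pos] == ":":
            pos += 1
            while pos < len(s) and s[pos] not in "(),;":
                pos += 1
        return label

    parse_node()
    if pos != len(s):
        raise ValidationError(f"trailing characters in eNewick: {text!r}")
    return RootedNetwork(g)
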