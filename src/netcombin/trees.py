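"""Rooted phylogenetic trees: model, Newick I/O, heights, triplet consistency.

Trees here are rooted, leaf-labeled, and possibly multifurcating (internal
nodes may have more than two children before binarization).  The height
function of a tree, h_T(i, j) = l_T - d_T(r, lca(i, j)), drives both the
triplet-consistency test and the HBUILD reconstruction: a triplet ij|k is
consistent with T exactly when h_T(i, j) < h_T(i, k) or
h_T(i, j) < h_T(j, k), i.e. when the cherry pair diverged strictly below
the pair's join with the outgroup.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterator

from .errors import ValidationError
from .heights import PairHeights, pair_key
from .triplets import Triplet, TripletSet

__all__ = [
    "TreeNode",
    "RootedTree",
    "tree_height",
    "is_consistent_tree",
    "triplets_of_tree",
    "parse_newick",
]


class TreeNode:
    """A node of a rooted tree: a leaf (label set) or an internal node (children)."""

    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children: list["TreeNode"] | None = None):
        self.label = label
        self.children: list[TreeNode] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset((self.label,))
        return frozenset(lab for c in self.children for lab in c.leaf_labels())

    def copy(self) -> "TreeNode":
        if self.is_leaf:
            return TreeNode(self.label)
        return TreeNode(children=[c.copy() for c in self.children])

    def __repr__(self) -> str:
        return f"TreeNode({_newick_of(self)})"


def _newick_of(node: TreeNode) -> str:
    if node.is_leaf:
        return node.label
    # canonical child order: by smallest descendant label
    parts = sorted((_newick_of(c) for c in node.children), key=_min_label_of_newick)
    return "(" + ",".join(parts) + ")"


def _min_label_of_newick(s: str) -> str:
    return min(x for x in s.replace("(", ",").replace(")", ",").split(",") if x)


class RootedTree:
    """A rooted leaf-labeled tree with at least one node.

    Leaves carry distinct taxon labels; internal nodes have out-degree >= 2
    (binary trees: exactly 2).  Equality is topology equality via the
    canonical Newick form.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.iter_nodes():
            if node.is_leaf:
                if not node.label:
                    raise ValidationError("leaf without a label")
                if node.label in seen:
                    raise ValidationError(f"duplicate leaf label {node.label!r}")
                seen.add(node.label)
            elif len(node.children) < 2:
                raise ValidationError("internal node with out-degree < 2")

    # -- construction helpers -------------------------------------------------
    @classmethod
    def leaf(cls, label: str) -> "RootedTree":
        return cls(TreeNode(label))

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        return cls(parse_newick(text))

    # -- structure ------------------------------------------------------------
    def iter_nodes(self) -> Iterator[TreeNode]:
        """Pre-order traversal."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaf_set(self) -> frozenset[str]:
        return self.root.leaf_labels()

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_set())

    def is_binary(self) -> bool:
        return all(
            node.is_leaf or len(node.children) == 2 for node in self.iter_nodes()
        )

    def copy(self) -> "RootedTree":
        return RootedTree(self.root.copy())

    # -- representation -------------------------------------------------------
    def newick(self) -> str:
        """Canonical Newick string (children sorted by smallest descendant label)."""
        return _newick_of(self.root) + ";"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RootedTree):
            return NotImplemented
        return self.newick() == other.newick()

    def __hash__(self) -> int:
        return hash(self.newick())

    def __repr__(self) -> str:
        return f"RootedTree({self.newick()!r})"


# -- Newick parsing ----------------------------------------------------------

def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string (no branch lengths required; any given are ignored)."""
    s = text.strip()
    if s.endswith(";"):
        s = s[:-1]
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            pos += 1
            children = [parse_node()]
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(parse_node())
            if pos >= len(s) or s[pos] != ")":
                raise ValidationError(f"unbalanced parentheses in Newick: {text!r}")
            pos += 1
            _consume_label()  # internal node labels are ignored
            return TreeNode(children=children)
        label = _consume_label()
        if not label:
            raise ValidationError(f"empty label at position {pos} in Newick: {text!r}")
        return TreeNode(label)

    def _consume_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        label = s[start:pos]
        if pos < len(s) and s[pos] == ":":  # skip branch length
            pos += 1
            while pos < len(s) and s[pos] not in "(),;":
                pos += 1
        return label

    node = parse_node()
    if pos != len(s):
        raise ValidationError(f"trailing characters in Newick: {text!r}")
    return node


# -- heights and consistency --------------------------------------------------

def tree_height(tree: RootedTree) -> PairHeights:
    """The height function h_T(i, j) = l_T - d_T(r, lca(i, j)).

    l_T is the number of edges on the longest root-to-leaf path; the LCA
    depth is collected while recursing (leaf pairs joining at a node of depth
    d have their lowest common ancestor there).
    """
    if tree.n_leaves < 2:
        raise ValidationError("height function needs at least 2 leaves")
    values: dict[tuple[str, str], int] = {}
    depth_of_lca: dict[tuple[str, str], int] = {}
    max_depth = 0

    def walk(node: TreeNode, depth: int) -> frozenset[str]:
        nonlocal max_depth
        max_depth = max(max_depth, depth)
        if node.is_leaf:
            return frozenset((node.label,))
        child_sets = [walk(c, depth + 1) for c in node.children]
        for a_set, b_set in combinations(child_sets, 2):
            for i in a_set:
                for j in b_set:
                    depth_of_lca[pair_key(i, j)] = depth
        return frozenset().union(*child_sets)

    walk(tree.root, 0)
    for key, d in depth_of_lca.items():
        values[key] = max_depth - d
    return PairHeights(values, max_depth)


def is_consistent_tree(t: Triplet, tree: RootedTree, heights: PairHeights | None = None) -> bool:
    """Exact triplet-against-tree consistency via the height characterization.

    For multifurcating trees the strict inequalities make no triplet of an
    unresolved 3-subset consistent (a star carries no information).
    """
    leaves = tree.leaf_set()
    if not t.labels <= leaves:
        missing = sorted(t.labels - leaves)
        raise ValidationError(f"labels {missing} not in the tree")
    h = heights if heights is not None else tree_height(tree)
    hij = h.get(t.i, t.j)
    return hij < h.get(t.i, t.k) or hij < h.get(t.j, t.k)


def triplets_of_tree(tree: RootedTree) -> TripletSet:
    """All triplets consistent with the tree: tau(T).

    For a binary tree on n leaves this has exactly C(n, 3) members (one
    resolved triplet per 3-subset).
    """
    leaves = sorted(tree.leaf_set())
    if len(leaves) < 3:
        raise ValidationError("triplet extraction needs at least 3 leaves")
    h = tree_height(tree)
    found: list[Triplet] = []
    for x, y, z in combinations(leaves, 3):
        for i, j, k in ((x, y, z), (x, z, y), (y, z, x)):
            if h.get(i, j) < h.get(i, k) or h.get(i, j) < h.get(j, k):
                found.append(Triplet(i, j, k))
    return TripletSet(found, universe=leaves)
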