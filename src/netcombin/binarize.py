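"""Binarization of multifurcating trees guided by triplet-support measures.

Refining a multifurcation never loses consistent triplets (the superset law
tau(T) is contained in tau(T_binary)), so binarization is a free opportunity
to gain consistency.  Each node with more than two children is resolved
agglomeratively: child subtrees are merged pairwise, the pair to merge
chosen by one of nine measures over the counts

* w -- triplets whose cherry straddles the two leaf sets and whose outgroup
  lies outside both (support for merging),
* p -- triplets placing one set's member in a cherry with an outsider and
  the other set's member as outgroup (evidence against merging),
* t -- triplets whose cherry straddles the two sets, regardless of the
  outgroup's position.

After each merge, six local subtree-prune-regraft (SPR) rearrangements of
the merged pair are proposed and the variant displaying the most input
triplets (the plain merge wins ties) is kept.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from typing import Iterable

from .errors import ValidationError
from .trees import (
    RootedTree,
    TreeNode,
    is_consistent_tree,
    tree_height,
    triplets_of_tree,
)
from .triplets import TripletSet

__all__ = [
    "MEASURES",
    "WtpCounts",
    "wtp_counts",
    "measure_value",
    "spr_variants",
    "count_consistent",
    "binarize",
]

MEASURES = ("m1", "m2", "m3", "m4", "m5", "m6", "m7", "m8", "m9")


class WtpCounts:
    """The (w, t, p) triplet-support counts for a pair of disjoint leaf sets."""

    __slots__ = ("w", "t", "p")

    def __init__(self, w: int, t: int, p: int):
        self.w = w
        self.t = t
        self.p = p

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WtpCounts):
            return NotImplemented
        return (self.w, self.t, self.p) == (other.w, other.t, other.p)

    def __repr__(self) -> str:
        return f"WtpCounts(w={self.w}, t={self.t}, p={self.p})"


def wtp_counts(v_i: Iterable[str], v_j: Iterable[str], tau: TripletSet) -> WtpCounts:
    """Count the supporting (w), total-cherry (t) and penalizing (p) triplets.

    t deliberately places no restriction on the outgroup, so w <= t always
    holds but t may also count triplets whose outgroup lies inside the union.
    """
    a = frozenset(v_i)
    b = frozenset(v_j)
    if not a or not b:
        raise ValidationError("both leaf sets must be nonempty")
    if a & b:
        raise ValidationError("leaf sets must be disjoint")
    union = a | b
    w = t = p = 0
    for trip in tau:
        x, y, z = trip.i, trip.j, trip.k
        straddles = (x in a and y in b) or (x in b and y in a)
        if straddles:
            t += 1
            if z not in union:
                w += 1
            continue
        # p: cherry = {member of one set, outsider}, outgroup in the other set
        for c1, c2 in ((x, y), (y, x)):
            if c2 in union:
                continue
            if (c1 in a and z in b) or (c1 in b and z in a):
                p += 1
                break
    return WtpCounts(w, t, p)


def _safe_div(num: int, den: int) -> Fraction:
    """Fractional term with a zero-denominator guard: x/0 contributes 0."""
    return Fraction(0) if den == 0 else Fraction(num, den)


def measure_value(measure: str, c: WtpCounts) -> Fraction:
    """Evaluate one of the nine merge measures on (w, t, p) counts."""
    w, t, p = c.w, c.t, c.p
    if measure == "m1":
        return Fraction(t)
    if measure == "m2":
        return Fraction(w)
    if measure == "m3":
        return Fraction(w - p)
    if measure == "m4":
        return _safe_div(w, w + p)
    if measure == "m5":
        return _safe_div(w, t)
    if measure == "m6":
        return _safe_div(w - p, w + p)
    if measure == "m7":
        return _safe_div(w - p, t)
    if measure == "m8":
        return Fraction(w - p) + _safe_div(w, t)
    if measure == "m9":
        return _safe_div(w - p, t) + _safe_div(w, w + p)
    raise ValidationError(f"unknown measure {measure!r}")


# --------------------------------------------------------------------------
# SPR variants around a merged pair
# --------------------------------------------------------------------------

def spr_variants(merged: TreeNode) -> list[TreeNode]:
    """The up-to-six local SPR rearrangements of a freshly merged pair.

    ``merged`` is a binary node with child subtrees c_i, c_j.  Writing
    c_lk / c_rk for the two children of c_k, the swaps are
    c_i<->c_lj, c_i<->c_rj, c_j<->c_li, c_j<->c_ri, c_li<->c_lj and
    c_li<->c_rj; any swap naming a child of a leaf (or of a still-unresolved
    multifurcating subtree, which has no left/right pair) is skipped.
    Variants share subtree nodes with the input; only the scaffolding is
    fresh.
    """
    if len(merged.children) != 2:
        raise ValidationError("SPR variants need a binary merged structure")
    c_i, c_j = merged.children
    i_split = len(c_i.children) == 2
    j_split = len(c_j.children) == 2
    out: list[TreeNode] = []

    def pair(a: TreeNode, b: TreeNode) -> TreeNode:
        return TreeNode(children=[a, b])

    if j_split:
        c_lj, c_rj = c_j.children
        out.append(pair(c_lj, pair(c_i, c_rj)))       # c_i <-> c_lj
        out.append(pair(pair(c_lj, c_i), c_rj))       # c_i <-> c_rj
    if i_split:
        c_li, c_ri = c_i.children
        out.append(pair(pair(c_j, c_ri), c_li))       # c_j <-> c_li
        out.append(pair(pair(c_li, c_j), c_ri))       # c_j <-> c_ri
    if i_split and j_split:
        c_li, c_ri = c_i.children
        c_lj, c_rj = c_j.children
        out.append(pair(pair(c_lj, c_ri), pair(c_li, c_rj)))  # c_li <-> c_lj
        out.append(pair(pair(c_rj, c_ri), pair(c_lj, c_li)))  # c_li <-> c_rj
    return out


def count_consistent(tree: RootedTree, tau: TripletSet) -> int:
    """Number of triplets of tau fully contained in and consistent with the tree."""
    leaves = tree.leaf_set()
    if len(leaves) < 2:
        return 0
    h = tree_height(tree) if len(leaves) >= 2 else None
    n = 0
    for t in tau:
        if t.labels <= leaves and is_consistent_tree(t, tree, heights=h):
            n += 1
    return n


def _count_consistent_node(node: TreeNode, tau: TripletSet) -> int:
    return count_consistent(RootedTree(node), tau)


# --------------------------------------------------------------------------
# The agglomerative binarization loop
# --------------------------------------------------------------------------

def binarize(tree: RootedTree, tau: TripletSet, measure: str = "m2") -> RootedTree:
    """Resolve every multifurcation of ``tree`` into a binary structure.

    Nodes with more than two children are processed in pre-order.  For each,
    the child structures are merged pairwise: the pair maximizing the chosen
    measure is merged (ties prefer the pair whose combined sorted leaf-label
    tuple is lexicographically least), the SPR variants of the merge are
    scored by displayed-triplet count (the plain merge wins ties, then the
    fixed swap order), and the winner re-enters the pool.  The input tree is
    not modified.
    """
    if measure not in MEASURES:
        raise ValidationError(f"unknown measure {measure!r}")
    root = tree.root.copy()
    # Triplets the unresolved tree already displays must survive: SPR swaps
    # can split a subtree, so variants are filtered against this baseline
    # (the plain merge is a pure refinement and always passes).
    baseline = (
        triplets_of_tree(tree) if tree.n_leaves >= 3 else TripletSet(())
    )
    for node in _preorder(root):
        if len(node.children) > 2:
            resolved = _resolve_multifurcation(node.children, tau, measure, baseline)
            node.children = resolved.children
    return RootedTree(root)


def _preorder(root: TreeNode) -> list[TreeNode]:
    out: list[TreeNode] = []
    stack = [root]
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(reversed(node.children))
    return out


def _keeps_baseline(candidate: TreeNode, baseline: TripletSet) -> bool:
    """True iff every baseline triplet inside the candidate's leaves is displayed."""
    leaves = candidate.leaf_labels()
    inside = [t for t in baseline if t.labels <= leaves]
    if not inside:
        return True
    tree = RootedTree(candidate)
    h = tree_height(tree)
    return all(is_consistent_tree(t, tree, heights=h) for t in inside)


def _resolve_multifurcation(
    children: list[TreeNode],
    tau: TripletSet,
    measure: str,
    baseline: TripletSet,
) -> TreeNode:
    pool = list(children)
    while len(pool) > 1:
        best_pair: tuple[int, int] | None = None
        best_key = None
        for a, b in combinations(range(len(pool)), 2):
            counts = wtp_counts(
                pool[a].leaf_labels(), pool[b].leaf_labels(), tau
            )
            value = measure_value(measure, counts)
            tie = tuple(sorted(pool[a].leaf_labels() | pool[b].leaf_labels()))
            key = (-value, tie)
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (a, b)
        a, b = best_pair
        merged = TreeNode(children=[pool[a], pool[b]])
        candidates = [merged] + [
            v for v in spr_variants(merged) if _keeps_baseline(v, baseline)
        ]
        scores = [_count_consistent_node(c, tau) for c in candidates]
        winner = candidates[max(range(len(candidates)), key=lambda k: scores[k])]
        # max() returns the first index attaining the maximum: the plain
        # merge wins ties, then the fixed swap order.
        pool = [s for idx, s in enumerate(pool) if idx not in (a, b)]
        pool.append(winner)
    return pool[0]
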