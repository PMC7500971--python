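"""Tree construction: BUILD, HBUILD, and the three disconnection strategies.

BUILD is the classical recursive supertree algorithm: the connected
components of the Aho graph become the root's children, recursing on each
component; it halts when a multi-taxon component refuses to split, which
certifies that no tree displays all triplets.

HBUILD works top-down on the weighted complete graph (G, h) carrying a pair
height function: at each component the maximum-weight edge tier is removed,
and the resulting components become siblings.  If removal fails to split a
component, one of three disconnection strategies forces a partition:

* strategy I keeps removing successive maximum-weight tiers until the
  component falls apart;
* strategy II removes a global minimum-weight cut;
* strategy III inverts the weights (m -> w - m + 1, w the component
  maximum) and removes a minimum-weight cut of the inverted graph, which
  preferentially cuts the originally heavy edges.

Running all three yields up to three candidate trees for the same input.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal

import networkx as nx

from .errors import ValidationError
from .heights import PairHeights
from .pairgraph import aho_graph, build_pair_graph, height_from_dag, make_dag
from .trees import RootedTree, TreeNode
from .triplets import TripletSet

__all__ = [
    "Strategy",
    "BuildHalt",
    "build",
    "hbuild",
    "disconnect_component",
    "build_candidate_trees",
]

Strategy = Literal["I", "II", "III"]

# Components larger than this use Stoer-Wagner directly; below it all
# 2-partitions are enumerated so the documented tie-break is exact.
_EXACT_MINCUT_LIMIT = 15


@dataclass(frozen=True)
class BuildHalt:
    """Report returned when BUILD stops: no tree displays the triplets.

    ``component`` is the multi-taxon label set whose Aho graph stayed
    connected after restriction.
    """

    component: frozenset[str]

    def __bool__(self) -> bool:  # a halt is falsy so `if build(...)` reads naturally
        return False


# --------------------------------------------------------------------------
# BUILD
# --------------------------------------------------------------------------

def build(tau: TripletSet) -> RootedTree | BuildHalt:
    """The Aho BUILD algorithm; returns a tree or a :class:`BuildHalt` report."""
    labels = tau.leaf_set() | tau.universe
    if not labels:
        raise ValidationError("BUILD needs at least one taxon")
    result = _build_rec(tau, frozenset(labels))
    if isinstance(result, BuildHalt):
        return result
    return RootedTree(result)


def _build_rec(tau: TripletSet, labels: frozenset[str]) -> TreeNode | BuildHalt:
    if len(labels) == 1:
        return TreeNode(next(iter(labels)))
    if len(labels) == 2:
        a, b = sorted(labels)
        return TreeNode(children=[TreeNode(a), TreeNode(b)])
    ag = aho_graph(tau, labels)
    comps = sorted(nx.connected_components(ag), key=lambda c: min(c))
    if len(comps) == 1:
        return BuildHalt(frozenset(labels))
    children: list[TreeNode] = []
    for comp in comps:
        sub = _build_rec(tau.restrict(comp), frozenset(comp))
        if isinstance(sub, BuildHalt):
            return sub
        children.append(sub)
    return TreeNode(children=children)


# --------------------------------------------------------------------------
# HBUILD
# --------------------------------------------------------------------------

def _weighted_complete_graph(h: PairHeights, labels: Iterable[str]) -> nx.Graph:
    g = nx.Graph()
    labs = sorted(labels)
    g.add_nodes_from(labs)
    for i, j in combinations(labs, 2):
        g.add_edge(i, j, weight=h.get(i, j))
    return g


def hbuild(h: PairHeights, labels: Iterable[str], strategy: Strategy = "I") -> RootedTree:
    """Top-down tree construction from a pair height function.

    ``h`` must be defined on every pair of ``labels``.  The strategy only
    matters when a maximum-tier removal fails to disconnect a component.
    """
    labs = sorted(set(labels))
    if not labs:
        raise ValidationError("HBUILD needs at least one taxon")
    if strategy not in ("I", "II", "III"):
        raise ValidationError(f"unknown strategy {strategy!r}")
    g = _weighted_complete_graph(h, labs)
    return RootedTree(_hbuild_rec(g, strategy))


def _hbuild_rec(component: nx.Graph, strategy: Strategy) -> TreeNode:
    nodes = sorted(component.nodes())
    if len(nodes) == 1:
        return TreeNode(nodes[0])
    stripped = component.copy()
    max_w = max(d["weight"] for _, _, d in stripped.edges(data=True))
    stripped.remove_edges_from(
        [(u, v) for u, v, d in stripped.edges(data=True) if d["weight"] == max_w]
    )
    parts = sorted(nx.connected_components(stripped), key=lambda c: min(c))
    if len(parts) == 1:
        parts = [set(p) for p in disconnect_component(stripped, strategy)]
        parts.sort(key=min)
    children = [_hbuild_rec(stripped.subgraph(p).copy(), strategy) for p in parts]
    if len(children) == 1:  # cannot happen: strategies always split
        return children[0]
    return TreeNode(children=children)


def disconnect_component(component: nx.Graph, strategy: Strategy) -> list[frozenset[str]]:
    """Force a partition of a connected component that survived max-tier removal.

    The input is the component with its maximum tier already stripped yet
    still connected.  Strategy I may return more than two parts; II and III
    always return exactly two.
    """
    if component.number_of_nodes() < 2:
        raise ValidationError("disconnection needs at least 2 nodes")
    if strategy == "I":
        work = component.copy()
        while nx.is_connected(work):
            max_w = max(d["weight"] for _, _, d in work.edges(data=True))
            work.remove_edges_from(
                [(u, v) for u, v, d in work.edges(data=True) if d["weight"] == max_w]
            )
        return sorted(
            (frozenset(c) for c in nx.connected_components(work)), key=min
        )
    weights = {
        (u, v): d["weight"] for u, v, d in component.edges(data=True)
    }
    if strategy == "III":
        w = max(weights.values())
        weights = {e: w - m + 1 for e, m in weights.items()}
    side = _min_cut_side(component, weights)
    other = frozenset(component.nodes()) - side
    return sorted((side, other), key=min)


def _min_cut_side(component: nx.Graph, weights: dict[tuple[str, str], int]) -> frozenset[str]:
    """One side of a global minimum-weight cut.

    Small components enumerate every 2-partition so ties break toward the
    cut whose smaller side's sorted label tuple is lexicographically least;
    larger components fall back to Stoer-Wagner (deterministic but with an
    implementation-defined tie choice).
    """
    nodes = sorted(component.nodes())
    n = len(nodes)
    if n == 2:
        return frozenset((nodes[0],))
    if n <= _EXACT_MINCUT_LIMIT:
        best_side: frozenset[str] | None = None
        best_key: tuple[int, tuple[str, ...]] | None = None
        # iterate proper nonempty subsets containing nodes[0] (canonical halves)
        rest = nodes[1:]
        for mask in range(0, 2 ** len(rest) - 1):
            side = {nodes[0]} | {rest[b] for b in range(len(rest)) if mask >> b & 1}
            comp_side = set(nodes) - side
            cut = sum(
                w
                for (u, v), w in weights.items()
                if (u in side) != (v in side)
            )
            small = min(side, comp_side, key=lambda s: (len(s), tuple(sorted(s))))
            key = (cut, tuple(sorted(small)))
            if best_key is None or key < best_key:
                best_key = key
                best_side = frozenset(side)
        return best_side
    weighted = nx.Graph()
    weighted.add_nodes_from(nodes)
    for (u, v), w in weights.items():
        weighted.add_edge(u, v, weight=w)
    _, (side_a, _) = nx.stoer_wagner(weighted)
    return frozenset(side_a)


# --------------------------------------------------------------------------
# Candidate trees
# --------------------------------------------------------------------------

def build_candidate_trees(tau: TripletSet) -> list[RootedTree]:
    """The three HBUILD candidates (strategies I, II, III) for a triplet set.

    Pipeline: pair graph -> feedback-arc repair -> peeling heights -> HBUILD.
    Duplicates among the three results are retained; the runs are
    independent.
    """
    if len(tau.leaf_set()) < 3:
        raise ValidationError("candidate trees need at least 3 taxa")
    g = build_pair_graph(tau)
    repaired, _ = make_dag(g)
    h = height_from_dag(repaired)
    labels = tau.leaf_set()
    return [hbuild(h, labels, s) for s in ("I", "II", "III")]
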