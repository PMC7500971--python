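"""The pair graph G_tau, the Aho graph, MFAS repair, and the peeling heights.

G_tau has one node per unordered taxon pair and, for every triplet ij|k, the
arcs ij->ik and ij->jk: an arc u->v says "pair u must split strictly below
pair v".  A feasible height function exists exactly when G_tau is acyclic;
when it is not, a small feedback arc set is removed heuristically before the
peeling assignment computes the heights.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

import networkx as nx

from .errors import ValidationError
from .heights import PairHeights, pair_key
from .triplets import TripletSet

__all__ = [
    "build_pair_graph",
    "aho_graph",
    "is_dag",
    "make_dag",
    "longest_path_length",
    "height_from_dag",
]

Pair = tuple[str, str]


def build_pair_graph(tau: TripletSet) -> nx.DiGraph:
    """Build G_tau on all C(n, 2) unordered pairs of L(tau).

    Isolated pair nodes are retained; parallel arcs collapse (DiGraph).
    """
    leaves = sorted(tau.leaf_set())
    if len(leaves) < 3:
        raise ValidationError("pair graph needs at least 3 taxa")
    g = nx.DiGraph()
    g.add_nodes_from(pair_key(i, j) for i, j in combinations(leaves, 2))
    for t in tau:
        src = pair_key(t.i, t.j)
        g.add_edge(src, pair_key(t.i, t.k))
        g.add_edge(src, pair_key(t.j, t.k))
    return g


def aho_graph(tau: TripletSet, labels: Iterable[str]) -> nx.Graph:
    """The Aho graph on ``labels``: i ~ j iff some ij|x lies in tau restricted to labels."""
    a = frozenset(labels)
    g = nx.Graph()
    g.add_nodes_from(sorted(a))
    for t in tau:
        if t.labels <= a:
            g.add_edge(t.i, t.j)
    return g


def is_dag(g: nx.DiGraph) -> bool:
    """Standard acyclicity test."""
    return nx.is_directed_acyclic_graph(g)


def _strip_periphery(g: nx.DiGraph) -> nx.DiGraph:
    """Iteratively remove in-degree-0 then out-degree-0 nodes; the cyclic core remains."""
    h = g.copy()
    changed = True
    while changed:
        changed = False
        for degree_view in (h.in_degree, h.out_degree):
            while True:
                doomed = [v for v, d in degree_view() if d == 0]
                if not doomed:
                    break
                h.remove_nodes_from(doomed)
                changed = True
    return h


def _wave_remaining_arcs(core: nx.DiGraph, v: Pair) -> set[tuple[Pair, Pair]]:
    """Run the black/white wave from v; return the arcs NOT removed by the wave.

    The wave removes v's out-arcs, blackens the heads, then repeatedly removes
    every arc from a black node to a still-white head (blackening the heads
    after each wave) until no black-to-white arc is left.  The arcs surviving
    the process are the candidate feedback set for v.
    """
    remaining = set(core.edges())
    black = {v}
    frontier = set()
    for _, head in core.out_edges(v):
        remaining.discard((v, head))
        frontier.add(head)
    black |= frontier
    while True:
        wave = [
            (x, y)
            for (x, y) in remaining
            if x in black and y not in black
        ]
        if not wave:
            break
        for arc in wave:
            remaining.discard(arc)
        black.update(y for _, y in wave)
    return remaining


def make_dag(g: nx.DiGraph) -> tuple[nx.DiGraph, set[tuple[Pair, Pair]]]:
    """Heuristically delete a small feedback arc set so the pair graph is acyclic.

    Each pass isolates the cyclic core (periphery stripping on a working
    copy), scores every core node v by the number of arcs the black/white
    wave started at v fails to remove, and deletes the minimum-score node's
    surviving arcs from the original graph.  Ties go to the lexicographically
    smallest pair node.  A single pass suffices in practice; the loop is
    defensive.  Returns the repaired graph and all deleted arcs.
    """
    repaired = g.copy()
    removed: set[tuple[Pair, Pair]] = set()
    while not is_dag(repaired):
        core = _strip_periphery(repaired)
        best: set[tuple[Pair, Pair]] | None = None
        best_key: tuple[int, Pair] | None = None
        for v in sorted(core.nodes()):
            remaining = _wave_remaining_arcs(core, v)
            key = (len(remaining), v)
            if best_key is None or key < best_key:
                best_key = key
                best = remaining
        if not best:
            raise ValidationError("cyclic graph but the wave heuristic found no arcs")
        repaired.remove_edges_from(best)
        removed |= best
    return repaired, removed


def longest_path_length(g: nx.DiGraph) -> int:
    """Number of arcs on a longest directed path (0 for arcless graphs)."""
    if not is_dag(g):
        raise ValidationError("longest path is only defined on a DAG")
    if g.number_of_nodes() == 0:
        return 0
    return nx.dag_longest_path_length(g)


def height_from_dag(g: nx.DiGraph) -> PairHeights:
    """The peeling height assignment on a repaired pair graph.

    Round r (from 0) assigns l+1-r to the current out-degree-0 nodes and
    removes them, where l is the longest directed path length.  Every arc
    u->v then satisfies value(u) < value(v), so every surviving triplet's
    constraints hold.
    """
    if not is_dag(g):
        raise ValidationError("heights require an acyclic pair graph")
    l = longest_path_length(g)
    work = g.copy()
    values: dict[Pair, int] = {}
    value = l + 1
    while work.number_of_nodes():
        sinks = [v for v, d in work.out_degree() if d == 0]
        for v in sinks:
            values[v] = value
        work.remove_nodes_from(sinks)
        value -= 1
    return PairHeights(values, l)
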