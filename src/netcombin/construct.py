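"""Network construction: valued edge-pair augmentation and the full pipeline.

Starting from a binary tree, edges are added one at a time until every input
triplet is displayed.  Each candidate addition subdivides an edge e with a
new tree node n_e and an edge f with a new reticulation node n_f, joined by
the arc n_e -> n_f; the pair committed is the one whose tentative network
displays the most still-missing triplets.  The full pipeline runs three
HBUILD strategies times nine binarization measures, augments each of the 27
binary trees, and reports the network with the fewest reticulations (ties:
lowest level, then fewest edges, then candidate order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .binarize import MEASURES, binarize
from .errors import NetcombinError, ValidationError
from .network import (
    RootedNetwork,
    consistent_triplet_set,
    level,
    reticulation_count,
    triplet_embeds,
)
from .pairgraph import build_pair_graph, height_from_dag, make_dag
from .treebuild import Strategy, hbuild
from .trees import RootedTree
from .triplets import TripletSet

__all__ = ["pair_value", "augment", "select_best", "netcombin_run", "RunReport"]

Edge = tuple[object, object]

# sentinel ids for tentative subdivision nodes; tuples cannot collide with
# taxon labels (str) or internal ids (int)
_NE = ("n_e",)
_NF = ("n_f",)


def _edge_order(net: RootedNetwork) -> list[Edge]:
    return sorted(net.graph.edges(), key=lambda e: (str(e[0]), str(e[1])))


def _fresh_id(g: nx.DiGraph) -> int:
    ints = [n for n in g.nodes() if isinstance(n, int)]
    return (max(ints) + 1) if ints else 0


def _with_added_edge(net: RootedNetwork, e: Edge, f: Edge) -> RootedNetwork | None:
    """Subdivide e (new tree node) and f (new reticulation), add n_e -> n_f.

    Returns None when the result would be cyclic; node classes are valid by
    construction otherwise.
    """
    g = net.graph.copy()
    base = _fresh_id(g)
    n_e, n_f = base, base + 1
    g.remove_edge(*e)
    g.add_edge(e[0], n_e)
    g.add_edge(n_e, e[1])
    g.remove_edge(*f)
    g.add_edge(f[0], n_f)
    g.add_edge(n_f, f[1])
    g.add_edge(n_e, n_f)
    if not nx.is_directed_acyclic_graph(g):
        return None
    return RootedNetwork(g, validate=False)


def _replace(neighbors: tuple, old, new) -> tuple:
    return tuple(new if x == old else x for x in neighbors)


def _tentative_maps(succ: dict, pred: dict, e: Edge, f: Edge) -> tuple[dict, dict]:
    """Adjacency maps of the tentative network, without building a graph."""
    a, b = e
    c, d = f
    succ2 = dict(succ)
    pred2 = dict(pred)
    succ2[a] = _replace(succ2[a], b, _NE)
    succ2[c] = _replace(succ2[c], d, _NF)
    succ2[_NE] = (b, _NF)
    succ2[_NF] = (d,)
    pred2[b] = _replace(pred2[b], a, _NE)
    pred2[d] = _replace(pred2[d], c, _NF)
    pred2[_NE] = (a,)
    pred2[_NF] = (c, _NE)
    return succ2, pred2


def pair_value(net: RootedNetwork, e: Edge, f: Edge, tau_rem: TripletSet) -> int | None:
    """Value of the ordered edge pair (e, f): missing triplets the addition fixes.

    Returns None when the pair is infeasible (the new arc would close a
    directed cycle).
    """
    edges = set(net.graph.edges())
    if e not in edges or f not in edges:
        raise ValidationError("both edges must belong to the network")
    if e == f:
        raise ValidationError("the two edges must differ")
    if e[0] == f[1] or e[0] in nx.descendants(net.graph, f[1]):
        return None
    succ, pred = net.adjacency_maps()
    succ2, pred2 = _tentative_maps(succ, pred, e, f)
    anc_cache: dict = {}
    return sum(
        1
        for t in tau_rem
        if triplet_embeds(succ2, pred2, t.i, t.j, t.k, anc_cache)
    )


def _inconsistent(net: RootedNetwork, tau: TripletSet) -> TripletSet:
    good = consistent_triplet_set(net, tau)
    return TripletSet((t for t in tau if t not in good), universe=tau.universe)


def _best_addition(net: RootedNetwork, remaining: TripletSet) -> RootedNetwork | None:
    """Evaluate every feasible ordered edge pair; return the best committed network.

    Ties go to the first pair in the canonical enumeration (edges sorted by
    stringified endpoints).  The scan stops early once a pair fixes every
    missing triplet, which cannot change the winner.  Returns None when no
    pair fixes anything.
    """
    succ, pred = net.adjacency_maps()
    # reach[x] = x plus everything reachable from x, for O(1) cycle tests
    order = list(nx.topological_sort(net.graph))
    reach: dict[object, frozenset] = {}
    for n in reversed(order):
        reach[n] = frozenset((n,)).union(*(reach[s] for s in succ[n]))
    rem_list = sorted(remaining)
    target = len(rem_list)
    edges = _edge_order(net)
    best_val = 0
    best_pair: tuple[Edge, Edge] | None = None
    for e in edges:
        for f in edges:
            if e == f or e[0] in reach[f[1]]:
                continue
            succ2, pred2 = _tentative_maps(succ, pred, e, f)
            anc_cache: dict = {}
            val = sum(
                1
                for t in rem_list
                if triplet_embeds(succ2, pred2, t.i, t.j, t.k, anc_cache)
            )
            if val > best_val:
                best_val = val
                best_pair = (e, f)
                if best_val == target:
                    break
        if best_val == target:
            break
    if best_pair is None:
        return None
    committed = _with_added_edge(net, *best_pair)
    assert committed is not None  # feasibility was pre-checked
    return committed


def augment(t_bin: RootedTree, tau: TripletSet) -> RootedNetwork:
    """Add edges to a binary tree until every triplet of tau is displayed.

    Each round commits the highest-value feasible ordered edge pair.  If no
    pair fixes any missing triplet, a fallback gadget subdivides the pendant
    edges of a missing triplet's cherry leaves and joins them, which
    realizes that cherry directly and guarantees progress.
    """
    if t_bin.leaf_set() != tau.leaf_set():
        raise ValidationError("tree leaves must equal the triplet label set")
    net = RootedNetwork.from_tree(t_bin)
    remaining = _inconsistent(net, tau)
    while len(remaining):
        committed = _best_addition(net, remaining)
        if committed is None:
            committed = _fallback_gadget(net, remaining)
        net = committed
        new_remaining = _inconsistent(net, remaining)
        if len(new_remaining) >= len(remaining):  # defensive; cannot happen
            raise NetcombinError("augmentation made no progress")
        remaining = new_remaining
    return net


def _fallback_gadget(net: RootedNetwork, remaining: TripletSet) -> RootedNetwork:
    """Directly realize the cherry of some missing triplet via its pendant edges."""
    for t in sorted(remaining):
        for i, j in ((t.i, t.j), (t.j, t.i)):
            e = next(iter(net.graph.in_edges(i)))
            f = next(iter(net.graph.in_edges(j)))
            tentative = _with_added_edge(net, e, f)
            if tentative is None:
                continue
            if len(consistent_triplet_set(tentative, TripletSet((t,)))) == 1:
                return tentative
    raise NetcombinError("no fallback addition makes any missing triplet consistent")


def select_best(candidates: list[RootedNetwork]) -> RootedNetwork:
    """Fewest reticulations; ties by level, then edge count, then list order."""
    if not candidates:
        raise ValidationError("no candidate networks to select from")
    best = candidates[0]
    best_key = (
        reticulation_count(best),
        level(best),
        best.graph.number_of_edges(),
    )
    for cand in candidates[1:]:
        key = (
            reticulation_count(cand),
            level(cand),
            cand.graph.number_of_edges(),
        )
        if key < best_key:
            best, best_key = cand, key
    return best


@dataclass
class RunReport:
    """Per-run diagnostics for the 27-candidate pipeline."""

    removed_arcs: list[tuple] = field(default_factory=list)
    candidates: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "removed_arcs": [
                [list(u), list(v)] for (u, v) in sorted(self.removed_arcs)
            ],
            "candidates": self.candidates,
        }


def netcombin_run(
    tau: TripletSet,
    strategies: tuple[Strategy, ...] = ("I", "II", "III"),
    measures: tuple[str, ...] = MEASURES,
) -> tuple[RootedNetwork, RunReport]:
    """The full pipeline: heights -> 3 trees -> 9 binarizations -> augment -> pick.

    The (strategy x measure) candidates are independent and individually
    deterministic, so identical binary trees share one augmentation run.
    The returned network displays every input triplet.
    """
    if len(tau.leaf_set()) < 3:
        raise ValidationError("the pipeline needs at least 3 taxa")
    g = build_pair_graph(tau)
    repaired, removed = make_dag(g)
    h = height_from_dag(repaired)
    labels = tau.leaf_set()
    report = RunReport(removed_arcs=sorted(removed))

    networks: list[RootedNetwork] = []
    cache: dict[str, RootedNetwork] = {}
    for strategy in strategies:
        t_int = hbuild(h, labels, strategy)
        for measure in measures:
            t_bin = binarize(t_int, tau, measure)
            key = t_bin.newick()
            if key not in cache:
                cache[key] = augment(t_bin, tau)
            net = cache[key]
            networks.append(net)
            report.candidates.append(
                {
                    "strategy": strategy,
                    "measure": measure,
                    "reticulations": reticulation_count(net),
                    "level": level(net),
                    "edges_added": reticulation_count(net),
                }
            )
    best = select_best(networks)
    missing = _inconsistent(best, tau)
    if len(missing):  # master postcondition; cannot happen
        raise NetcombinError(f"output network misses {len(missing)} triplets")
    return best, report
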