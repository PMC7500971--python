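"""Synthetic data: random trees, random level-k networks, triplet extraction.

The generator stands in for sequence-level benchmark data at the triplet
level: a uniform random rooted binary topology is drawn, k random feasible
edge additions turn it into a network with exactly k reticulations, and the
set of triplets the network displays (optionally subsampled) becomes the
pipeline input.  Everything is driven by one seeded generator, so a run is
reproducible from (n, k, seed) alone.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations

from .construct import _with_added_edge
from .errors import ValidationError
from .network import RootedNetwork, consistent_triplet_set
from .trees import RootedTree, TreeNode
from .triplets import Triplet, TripletSet

__all__ = ["SimConfig", "simulate_tree", "simulate_network", "extract_triplets"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic instance."""

    taxa: int
    reticulations: int = 0
    seed: int = 0
    sample_fraction: float = 1.0

    def __post_init__(self):
        if self.taxa < 3:
            raise ValidationError("need at least 3 taxa")
        if self.reticulations < 0:
            raise ValidationError("reticulation count must be >= 0")
        if not 0 < self.sample_fraction <= 1:
            raise ValidationError("sample fraction must lie in (0, 1]")


def _labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"t{idx:0{width}d}" for idx in range(1, n + 1)]


def simulate_tree(n: int, seed: int | random.Random = 0) -> RootedTree:
    """Uniform random rooted binary topology on n labeled leaves.

    Sequential random attachment: leaf m+1 is grafted onto one of the 2m-1
    insertion points (every edge, or above the root) chosen uniformly, which
    yields the uniform distribution over the (2n-3)!! rooted binary shapes.
    """
    if n < 2:
        raise ValidationError("a tree needs at least 2 leaves")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    labels = _labels(n)
    root = TreeNode(labels[0])
    for label in labels[1:]:
        slots: list[tuple[TreeNode, int]] = []  # (parent, child index)
        stack = [root]
        while stack:
            node = stack.pop()
            for idx, child in enumerate(node.children):
                slots.append((node, idx))
                stack.append(child)
        choice = rng.randrange(len(slots) + 1)
        new_leaf = TreeNode(label)
        if choice == len(slots):  # above the root
            root = TreeNode(children=[root, new_leaf])
        else:
            parent, idx = slots[choice]
            parent.children[idx] = TreeNode(children=[parent.children[idx], new_leaf])
    return RootedTree(root)


def simulate_network(n: int, k: int, seed: int | random.Random = 0) -> RootedNetwork:
    """A random network with exactly k reticulations on a random n-leaf tree.

    Each addition subdivides two edges (tree node / reticulation node) and
    joins them, drawn uniformly from the feasible (acyclic) ordered pairs.
    """
    if n < 2:
        raise ValidationError("a network needs at least 2 leaves")
    if k < 0:
        raise ValidationError("reticulation count must be >= 0")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    net = RootedNetwork.from_tree(simulate_tree(n, rng))
    for _ in range(k):
        edges = sorted(net.graph.edges(), key=lambda e: (str(e[0]), str(e[1])))
        while True:  # rejection sampling keeps the draw uniform over feasible pairs
            e, f = rng.choice(edges), rng.choice(edges)
            if e == f:
                continue
            tentative = _with_added_edge(net, e, f)
            if tentative is not None:
                net = tentative
                break
    net.validate()
    return net


def extract_triplets(
    net: RootedNetwork, fraction: float = 1.0, seed: int | random.Random = 0
) -> TripletSet:
    """The triplets the network displays, uniformly subsampled to ``fraction``.

    ``fraction=1`` returns tau(N) exactly; note a reticulate network may
    display more than one triplet per 3-subset of leaves.
    """
    leaves = net.leaves()
    if len(leaves) < 3:
        raise ValidationError("triplet extraction needs at least 3 leaves")
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must lie in (0, 1]")
    candidates = [
        Triplet(i, j, k)
        for x, y, z in combinations(leaves, 3)
        for i, j, k in ((x, y, z), (x, z, y), (y, z, x))
    ]
    consistent = consistent_triplet_set(
        net, TripletSet(candidates, universe=leaves)
    )
    if fraction == 1:
        return consistent
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    pool = sorted(consistent)
    keep = rng.sample(pool, max(1, round(fraction * len(pool))))
    return TripletSet(keep, universe=leaves)
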