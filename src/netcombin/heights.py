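"""Height functions on unordered taxon pairs.

A height function maps each unordered pair {i, j} of a taxon set to a
positive integer encoding how deep the pair's most recent common ancestor
sits relative to the deepest split: pairs that diverge near the leaves get
small values, pairs whose ancestor is the root get the largest.  Trees,
repaired pair graphs and networks all induce one, and HBUILD consumes one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = ["PairHeights", "pair_key"]


def pair_key(i: str, j: str) -> tuple[str, str]:
    """Canonical (sorted) key for the unordered pair {i, j}."""
    if i == j:
        raise ValueError(f"pair needs two distinct labels, got {i!r} twice")
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class PairHeights:
    """An integer-valued height function plus the longest-path length it came from.

    ``length`` is the longest directed path length of the originating
    structure (l_T, l_Gtau or l_N); all values lie in [1, length + 1].
    """

    values: Mapping[tuple[str, str], int]
    length: int

    def __getitem__(self, pair: tuple[str, str]) -> int:
        return self.values[pair_key(*pair)]

    def get(self, i: str, j: str) -> int:
        return self.values[pair_key(i, j)]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def labels(self) -> frozenset[str]:
        return frozenset(x for pair in self.values for x in pair)
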