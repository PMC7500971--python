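"""Rooted triplets and triplet sets.

A rooted triplet ``ij|k`` is the smallest informative rooted tree: it states
that taxa *i* and *j* share a more recent common ancestor with each other
than either does with the outgroup *k*.  Triplet sets are the input to the
whole network-construction pipeline.

The on-disk format is one triplet per line, three whitespace-separated
labels, the first two forming the cherry (``b c a`` means ``bc|a``).  Lines
starting with ``#`` are comments; blank lines are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator

from .errors import TripletParseError, ValidationError

__all__ = ["Triplet", "TripletSet", "parse_triplets", "write_triplets"]


@dataclass(frozen=True, order=True)
class Triplet:
    """The rooted triplet ``ij|k``: cherry {i, j}, outgroup k.

    The cherry is unordered: ``Triplet('i','j','k') == Triplet('j','i','k')``.
    Internally the cherry is stored lexicographically sorted so that equality
    and hashing are label-set based.
    """

    i: str
    j: str
    k: str

    def __init__(self, i: str, j: str, k: str):
        for lab in (i, j, k):
            if not lab or any(c.isspace() for c in lab):
                raise ValidationError(
                    f"taxon label {lab!r} must be non-empty and whitespace-free"
                )
        if len({i, j, k}) != 3:
            raise ValidationError(f"triplet labels must be distinct, got {i} {j} {k}")
        a, b = sorted((i, j))
        object.__setattr__(self, "i", a)
        object.__setattr__(self, "j", b)
        object.__setattr__(self, "k", k)

    @property
    def cherry(self) -> frozenset[str]:
        return frozenset((self.i, self.j))

    @property
    def labels(self) -> frozenset[str]:
        return frozenset((self.i, self.j, self.k))

    def __str__(self) -> str:  # canonical "ij|k" rendering
        return f"{self.i}{self.j}|{self.k}"


@dataclass(frozen=True)
class TripletSet:
    """A duplicate-free collection of triplets together with its taxon universe.

    The universe defaults to the label union L(tau) of the member triplets but
    may be explicitly widened (never narrowed).
    """

    triplets: frozenset[Triplet]
    universe: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __init__(self, triplets: Iterable[Triplet], universe: Iterable[str] | None = None):
        trips = frozenset(triplets)
        labels = frozenset(lab for t in trips for lab in t.labels)
        uni = labels if universe is None else frozenset(universe)
        if not labels <= uni:
            raise ValidationError("universe must contain every label used by a triplet")
        object.__setattr__(self, "triplets", trips)
        object.__setattr__(self, "universe", uni)

    def __iter__(self) -> Iterator[Triplet]:
        return iter(self.triplets)

    def __len__(self) -> int:
        return len(self.triplets)

    def __contains__(self, t: Triplet) -> bool:
        return t in self.triplets

    def leaf_set(self) -> frozenset[str]:
        """L(tau): the union of the labels of all member triplets."""
        return frozenset(lab for t in self.triplets for lab in t.labels)

    def restrict(self, labels: Iterable[str]) -> "TripletSet":
        """Triplets all three of whose labels lie in ``labels`` (tau|A)."""
        a = frozenset(labels)
        if not a <= self.universe:
            raise ValidationError("restriction set must be a subset of the universe")
        return TripletSet((t for t in self.triplets if t.labels <= a), universe=a)

    def is_dense(self) -> bool:
        """True iff every 3-subset of L(tau) carries at least one triplet.

        Density is the condition under which exact polynomial-time network
        construction is known; the pipeline itself does not require it.
        """
        leaves = self.leaf_set()
        if len(leaves) < 3:
            raise ValidationError("density needs at least 3 taxa")
        by_labels: set[frozenset[str]] = {t.labels for t in self.triplets}
        return all(
            frozenset(trio) in by_labels for trio in combinations(sorted(leaves), 3)
        )


def parse_triplets(text: str) -> TripletSet:
    """Parse the line-oriented triplet format into a :class:`TripletSet`.

    Duplicate lines (including cherry-order variants) collapse to a single
    triplet.  Raises :class:`TripletParseError` with the offending line number
    on malformed input.
    """
    triplets: list[Triplet] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 3:
            raise TripletParseError(
                f"expected 3 labels, got {len(tokens)}: {raw.strip()!r}", lineno
            )
        try:
            triplets.append(Triplet(*tokens))
        except ValidationError as exc:
            raise TripletParseError(str(exc), lineno) from exc
    return TripletSet(triplets)


def write_triplets(tau: TripletSet) -> str:
    """Canonical text rendering: sorted lines, cherry sorted; inverse of parse."""
    lines = sorted(f"{t.i} {t.j} {t.k}" for t in tau)
    return "".join(line + "\n" for line in lines)
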