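# Methods

This note records the model, the algorithmic choices that were genuinely
open, the defaults of the synthetic-data generator, and the limits of what
the test suite demonstrates.

## Problem and model

Input is a finite set τ of rooted triplets *ij*|*k* over a taxon set
*X* = *L*(τ). Output is a rooted phylogenetic network: a connected DAG with
one root (in 0, out 2), tree nodes (in 1, out 2), reticulation nodes
(in 2, out 1) and leaves (in 1, out 0) labeled bijectively by *X*. A
triplet is *consistent* with a network iff it embeds as a subdivision:
nodes *u*, *v* with pairwise internally node-disjoint paths *u*→*i*,
*u*→*j*, *v*→*u*, *v*→*k*. The construction must display every input
triplet; the quality criteria are the number of reticulations and the
level (maximum reticulations per biconnected component), in that order.
Exact minimization is NP-hard; everything past the consistency guarantee
is heuristic.

## Height functions

Three height functions share one shape (unordered pair → positive integer):

* tree: *h*<sub>T</sub>(*i*, *j*) = *l*<sub>T</sub> −
  *d*<sub>T</sub>(*r*, lca(*i*, *j*));
* repaired pair graph: the peeling assignment (sinks get *l*+1, are
  removed, next layer gets *l*, …);
* network: *h*<sub>N</sub>(*a*, *b*) = min over lowest common ancestors
  *c* of *l*<sub>N</sub> − *d*(*r*, *c*), where *d* is the **longest**-path
  distance from the root. On a tree-shaped network this reduces to
  *h*<sub>T</sub>.

The strict inequalities *h*(*i*, *j*) < *h*(*i*, *k*) or < *h*(*j*, *k*)
characterize tree consistency exactly and are a *sufficient* (not
necessary) condition for network consistency; the package uses the
sufficiency as a fast path and falls back to the exact embedding search.
For multifurcating trees the strict inequalities leave all three triplets
of an unresolved trio inconsistent — a star carries no information.

## Feedback-arc repair (wave heuristic)

When *G*<sub>τ</sub> is cyclic, the cyclic core is isolated on a working
copy (iterated stripping of in-degree-0 then out-degree-0 nodes; the
stripped periphery still needs heights, so only arcs are ever deleted from
the true graph). For each core node *v*, the black/white wave removes *v*'s
out-arcs, blackens the heads, and then repeatedly removes *every* arc from
a black node to a still-white head in one wave, blackening the new heads —
the singular phrasing of the procedure is read as iterating over all such
arcs, which is what the worked example depicts. Value(*v*) = arcs the wave
left behind; the minimum-Value node's surviving arcs are deleted (ties: the
lexicographically smallest pair node, which reproduces the worked example's
choice). One pass suffices in every case observed; the enclosing loop is
defensive. The removal count is a heuristic upper bound on the true minimum
feedback arc set, never below it (asserted against an exhaustive oracle on
small cores).

## HBUILD and the disconnection strategies

Max-weight tier removal is per-component (local maximum) at every recursion
level. When a component survives its tier removal, the strategies are:

* **I** — keep removing successive maximum tiers until the component falls
  apart; this may produce more than two parts, and all become siblings.
* **II** — global minimum-weight cut.
* **III** — invert weights (*m* → *w* − *m* + 1 with *w* the component
  maximum) and min-cut the inverted graph. The inversion makes originally
  light edges expensive, so this preferentially severs the heavy edges.

Minimum cuts on components of ≤ 15 nodes are found by exhaustive
2-partition enumeration with a deterministic tie-break (the cut whose
smaller side's sorted label tuple is lexicographically least); larger
components fall back to Stoer–Wagner, which is deterministic for a fixed
input but makes its own tie choices. With positive weights a minimum-cut
side is always connected, so recursion is well-founded. Strategy recursion
continues on the tier-stripped subgraphs; tiers removed *during* a
strategy-I search are allowed to reappear inside a part, where they are
immediately the part's next maximum tier — observationally equivalent on
all worked cases and simpler to state.

## Binarization

For disjoint leaf sets *V*<sub>i</sub>, *V*<sub>j</sub>: *w* counts
triplets whose cherry straddles the sets with the outgroup outside both;
*p* counts triplets pairing a member of one set with an outsider against
an outgroup in the other set; *t* counts straddling cherries regardless of
the outgroup (so the outgroup may lie inside the union — the definition is
kept as stated, and *w* ≤ *t* always holds). The nine measures are
m1 = *t*, m2 = *w*, m3 = *w*−*p*, m4 = *w*/(*w*+*p*), m5 = *w*/*t*,
m6 = (*w*−*p*)/(*w*+*p*), m7 = (*w*−*p*)/*t*, m8 = *w*−*p*+*w*/*t*,
m9 = (*w*−*p*)/*t* + *w*/(*w*+*p*), evaluated in exact rational
arithmetic. Any term with a zero denominator contributes 0, which keeps
every measure total.

Multifurcations are processed in pre-order; each is resolved by merging the
pair of child structures with the maximal measure (ties: lexicographically
least combined leaf tuple), then trying the six local SPR swaps of the
merged pair and keeping the variant displaying the most input triplets
(ties: the plain merge, then the fixed swap order). Swaps that would name a
child of a leaf — or of a still-unresolved multifurcating subtree, which
has no left/right pair — are skipped.

An SPR swap can split a formerly intact subtree and thereby lose a triplet
the unresolved tree already displayed, which would violate the refinement
law τ(T) ⊆ τ(T_binary). A variant is therefore only eligible if every
originally-displayed triplet inside its leaf set remains displayed; the
plain merge is a pure refinement and always qualifies, so the loop always
progresses and the law holds unconditionally. Only triplets fully contained
in the candidate subtree's leaves are scored, since a subtree rearrangement
cannot affect any other triplet.

## Augmentation

An addition subdivides edge *e* with a tree node n<sub>e</sub> and edge *f*
with a reticulation node n<sub>f</sub> and adds n<sub>e</sub>→n<sub>f</sub>;
it is feasible iff no directed cycle results (checked in O(1) per pair
against the precomputed reachability of the current network). Ordered pairs
are enumerated in a canonical edge order, each scored by how many
still-missing triplets the tentative network displays; the first
maximum-value pair is committed, and the scan stops early once a pair fixes
every missing triplet (no later pair could strictly beat it, so the winner
is unchanged). Consistency of previously displayed triplets is monotone
under this addition form, so only the missing set is rechecked. If no pair
fixes anything, a fallback subdivides the pendant edges of a missing
triplet's cherry and joins them, realizing that cherry directly; in
practice the main scan already contains these pairs, so the fallback is
defensive. Tentative networks are evaluated on plain adjacency dicts
(no graph copies) for speed.

## Selection

Among the 3 × 9 = 27 augmented networks: fewest reticulations, then lowest
level, then fewest edges, then candidate order. Reticulation count is
ranked before level; the two criteria are both reported per candidate in
the run report. Candidates are independent and individually deterministic,
so identical binary trees share one augmentation run; results equal the
fully sequential computation.

## Synthetic-data generator

`simulate_tree(n, seed)` draws a uniform rooted binary topology by
sequential random attachment (leaf *m*+1 grafts onto one of the 2*m*−1
insertion points). `simulate_network(n, k, seed)` adds *k* reticulation
edges drawn uniformly from the feasible ordered edge pairs by rejection
sampling, giving exactly *k* reticulations and level ≤ *k*.
`extract_triplets(net, fraction, seed)` returns the displayed triplet set,
optionally subsampled uniformly. One seeded generator drives all draws.

The generator emulates benchmark data only at the triplet level: it does
not model sequence evolution, inference error, star triplets or the
densification of sparse sets, so passing tests demonstrate correctness of
the combinatorial pipeline on noise-free displayed-triplet inputs, not
robustness to estimation error in real data. Problem sizes in the test
suite — up to 10 taxa and 2 reticulations for end-to-end runs, up to 8
taxa for the property sweeps — were chosen so each suite documents its
property at desk scale; the algorithms themselves have no such limits,
though the exact consistency check is exponential in the worst case and
the augmentation scan is quadratic in the edge count per round.

## Numerical and degenerate-input choices

* Measures use `fractions.Fraction`: no floating-point ties.
* All iteration orders (pair nodes, components, edges, children) are
  canonicalized by sorting, so every operation is deterministic; canonical
  Newick/eNewick output sorts children by smallest descendant label, and
  reticulation tags #H1, #H2, … are numbered by smallest reachable leaf.
* Empty triplet sets, two-taxon restrictions, arcless pair graphs and
  already-binary trees are all defined no-ops rather than errors; genuinely
  undecidable requests (density on < 3 taxa, heights on cyclic graphs)
  raise `ValidationError`.

## Known limitations

* The exact network-consistency decision enumerates candidate (u, v) pairs
  with backtracking; it is exact but exponential in pathological networks.
  It is exercised against a brute-force path-enumeration oracle only on
  small networks.
* The feedback-arc heuristic and the whole pipeline carry no approximation
  guarantee; only full consistency of the output is guaranteed.
* Weighted or partially resolved triplets and quartet inputs are out of
  scope.
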