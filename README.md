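# netcombin

Construction of rooted phylogenetic networks from rooted triplets.

A rooted triplet *ij*|*k* is the smallest informative statement about rooted
evolutionary history: taxa *i* and *j* are closer to each other than either
is to *k*. Triplet sets arise from maximum-likelihood analyses of taxon
trios, from database mining, or directly from experiments. When the triplets
conflict — as they do whenever hybridization, recombination or lateral gene
transfer shaped the history — no tree displays them all, and the object of
interest becomes a **rooted phylogenetic network**: a DAG with tree nodes
and *reticulation* nodes (in-degree 2). Finding a network consistent with
all given triplets while minimizing the number of reticulations or the
network *level* (reticulations per biconnected component) is NP-hard, so
practical tools are heuristic.

This package implements the Netcombin heuristic. For an input triplet set τ
on taxa *X*:

1. **Pair-graph heights.** The directed graph *G*<sub>τ</sub> has a node for
   every unordered pair {*i*, *j*} and arcs *ij*→*ik*, *ij*→*jk* for each
   triplet *ij*|*k*. If *G*<sub>τ</sub> is cyclic, a small feedback arc set
   is removed by a black/white wave heuristic. Peeling the DAG from its
   sinks assigns every pair a height *h*(*i*, *j*) ∈ [1, *l*+1], where *l*
   is the longest directed path length; every surviving triplet then
   satisfies *h*(*i*, *j*) < *h*(*i*, *k*) and *h*(*i*, *j*) < *h*(*j*, *k*).
2. **HBUILD.** On the complete graph over *X* weighted by *h*, repeatedly
   deleting each component's maximum-weight edge tier splits the taxa
   top-down into a tree. When a component refuses to split, one of three
   disconnection strategies forces a partition (further tier removal,
   minimum cut, or minimum cut on inverted weights), giving up to three
   candidate trees.
3. **Binarization.** Each multifurcation is resolved agglomeratively using
   one of nine measures over the triplet-support counts (*w*, *t*, *p*) of
   child leaf-set pairs, with six local subtree-prune-regraft rearrangements
   tried after every merge — 9 binary trees per candidate, 27 in total.
4. **Augmentation.** Each binary tree is grown into a network: every
   feasible ordered edge pair (*e*, *f*) is scored by how many missing
   triplets become consistent when *e* is subdivided by a tree node, *f* by
   a reticulation node, and the two are joined; the best addition is
   committed until all triplets are displayed. The network with the fewest
   reticulations (ties: lowest level) is reported.

Triplet consistency with a network is decided **exactly**: *ij*|*k* is
consistent with *N* iff *N* contains nodes *u*, *v* with pairwise internally
node-disjoint paths *u*→*i*, *u*→*j*, *v*→*u*, *v*→*k*.

## Worked example

The five triplets {*bc*|*a*, *bd*|*a*, *cd*|*a*, *bc*|*d*, *cd*|*b*} cannot
be displayed by any tree (BUILD halts on the component {*b*, *c*, *d*}):

```sh
$ printf 'b c a\nb d a\nc d a\nb c d\nc d b\n' > trip.txt
$ netcombin run trip.txt
read 5 triplets on 4 taxa
pair-graph repair removed 1 arcs
...
selected network: reticulations=1 level=1
(((((b)#H1,c),d),#H1),a);
```

The pair graph of these triplets contains the cycle *bc* → *cd* → *bc*; the
repair deletes the single arc (*cd*, *bc*), the peeled heights are
*h*(*a*,·) = 4, *h*(*b*, *d*) = 3, *h*(*c*, *d*) = 2, *h*(*b*, *c*) = 1,
and the pipeline returns a one-reticulation (level-1) network in which leaf
*c* is reachable from both sides of the split — the minimum possible, since
no tree exists. The `#H1` tag marks the reticulation in extended Newick:
the tagged subtree `(b)#H1` re-attaches where `#H1` reappears.

The same library surface is available programmatically:

```python
from netcombin import parse_triplets, netcombin_run, reticulation_count, level

net, report = netcombin_run(parse_triplets("b c a\nb d a\nc d a\nb c d\nc d b\n"))
print(reticulation_count(net), level(net))   # 1 1
```

Synthetic inputs come from the built-in generator
(`netcombin simulate --taxa 8 --ret 1 --seed 7 --out trip.txt`), which draws
a uniform random rooted binary topology, adds the requested number of random
reticulation edges, and writes the triplets the network displays.

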