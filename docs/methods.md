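# Methods

## Problem

A MUL tree is a rooted binary phylogenetic tree in which several leaves
may carry the same taxon label — the natural object when gene copies
from polyploid genomes, or parasite lineages sampled per host, are
relabeled by the species they belong to.  A rooted triplet `xy|z` states
that taxa x and y are closer to each other than either is to z; a
triplet is *consistent* with a MUL tree when some choice of one leaf
occurrence per label embeds it (the LCA of the chosen x and y leaves is
a proper descendant of the LCA of all three).  The SMRT problem asks for
a MUL tree on exactly the label set L, consistent with every triplet of
a given set, with the fewest leaf duplications
`dup(T) = n(T) − |M(T)|` (leaves minus distinct labels).  SMRT is
NP-hard; this package provides a polynomial heuristic (MTRT), an
exhaustive exact solver for small instances, and the instrumentation to
ask whether minimizing duplications recovers the tree the triplets came
from (the consistency principle).

## The MTRT heuristic (`multriplet.mtrt`)

MTRT extends the Aho et al. BUILD recursion.  At each level, the
*auxiliary graph* on the current labels has an edge {x, y} for every
triplet `xy|z`:

* **Disconnected graph** — group the components into two sides and
  recurse; this is BUILD and introduces no duplication.  Components are
  grouped greedily by decreasing size onto the currently smaller side
  (ties by lexicographically smallest member), because the output must
  be binary.
* **Connected graph** — BUILD would fail.  MTRT picks a minimum-size
  minimal vertex separator S, duplicates its labels onto both sides
  (L_i = X_i ∪ S for the grouped components X_i of G − S), and recurses.
* **Complete graph** — no separator exists.  One leaf x is hung directly
  off the root and every triplet with outgroup x is dropped; x is chosen
  to drop the most triplets (ties lexicographic).  The triplet set
  strictly shrinks, so this terminates, and the step costs at most one
  duplication (x stays in the recursive label set only if remaining
  triplets mention it).

Separator candidates come from a greedy variant of the Berry–Bordat
AllMinSep enumeration: the initial batch collects, for every vertex v,
the neighborhoods of the components of G − N[v]; expansion of a
separator S by a vertex x collects neighborhoods of the components of
G − (S ∪ N(x)).  A generated separator is kept only if its size does not
exceed the smallest size seen so far (the bound tightens as smaller
separators appear), so the enumeration stays polynomial per level while
still reaching minimum size on every graph we have probed (it matched
the true vertex connectivity on all randomized checks in the test
suite).  Among the minimum-size separators MTRT picks the one minimizing

    w(S) = alpha · |t(S)| / max(1, |t|)  +  ||L1| − |L2|| / |L'|

with `alpha = 2` by default: the first term penalizes triplets trapped
wholly inside the separator, the second rewards balanced splits.  Ties
are broken by the lexicographically smallest separator, making runs
fully deterministic.

### Which triplets cross a split

When the root splits the labels into (possibly overlapping) sides L1
and L2, any triplet whose cherry lies wholly inside one side while its
outgroup occurs on the other side is consistent with the assembled tree
*regardless of how the sides are built*: the cherry's LCA sits strictly
below the root and the outgroup hangs off the other root child.  Such
triplets are dropped; each remaining triplet has all three labels in
exactly one side and is passed there.  This drop rule subsumes the
narrower "triplets wholly inside the separator" rule (separator labels
sit on both sides), coincides with BUILD's behaviour when the graph is
disconnected, and is the reason every input triplet is consistent with
the output — a structural guarantee, re-verifiable with `check=True`.
Empirically it also matters for tree size: with the narrow rule each
side must re-satisfy triplets that the root split already realizes,
which we found to inflate duplication counts several-fold on densely
duplicated inputs.

When the induced triplet set of a subproblem is empty, any tree is
consistent; a caterpillar over the sorted labels is used for
determinism.

## The exact solver (`multriplet.exact_oracle`)

For duplication levels d = 0, 1, … the solver enumerates every leaf
multiset over L with d extra copies and searches rooted binary trees
over that multiset by inserting leaves one at a time onto every edge.
Leaf insertion never changes the relative topology of leaves already
placed, so once all copies of a triplet's three labels are present its
consistency is decided; branches violating any decided triplet are
pruned immediately.  The first consistent tree found (in a fixed
deterministic order) is returned, and is provably of minimum
duplication among trees within the budget.  Budgets (`max_labels = 7`,
`max_dup = 3`, plus an insertion-step cap) make refusal explicit: the
solver errors rather than answer wrongly.  `enumerate_multrees` exposes
the underlying exhaustive generator with canonical-form deduplication
((2m−3)!! shapes for m distinct leaves).

## Triplet encodings and distances (`multriplet.triplets`)

The multiplicity of `xy|z` in T is its number of embedded occurrence
triples, counted per internal node v as (x-leaves in one child subtree ×
y-leaves in the other) × (z-leaves outside v's subtree); the test suite
checks this against explicit LCA enumeration over all occurrence
triples.  Two distances compare trees on the same taxa set:

* `d_R = |t(T1) Δ t(T2)| / 2` — half the set symmetric difference of
  the triplet encodings;
* `d'_R = |mt(T1) Δ mt(T2)| / 2` — the multiset analogue, with
  per-element multiplicity `|m1(x) − m2(x)|`.

`d'_R ≥ d_R` always.  `d'_R` is a pseudometric, not a metric: distinct
MUL trees at distance 0 exist — the smallest witness found by exhaustive
search over trees with at most 6 leaves is `(((a,a),b),c)` vs
`(((a,b),a),c)`, both with triplet multiset {ab|c: 2}.  Neither
distance is normalized; the halving convention means one triplet present
on only one side contributes 1/2.

## The simulator (`multriplet.simulate`)

Synthetic MUL trees follow the standard gene-tree-in-species-tree
protocol: an ultrametric Yule species tree (birth rate `speciation_rate`,
default 1; after the n-th lineage appears an Exp(n·rate) stub runs to
the present, so the expected root depth is Σ_{k=2..n} 1/(k·rate)); a
uniform random assignment of gene copies to species with every species
receiving at least one; and a multispecies coalescent run by msprime
(ploidy 1, population size `theta`, so a lineage pair merges at rate
1/theta — deeper coalescence and hence more topological conflict for
larger theta).  Gene leaves are relabeled by their species, giving a MUL
tree with exactly `n_genes − n_species` duplications.  A provenance
record carries the species tree, divergence times, the assignment, and
every gene-tree coalescence with the species below its two children, so
tests can verify that lineages from two species never merge before those
species diverged.

The generator emulates duplication arising from multiple gene copies per
species under incomplete lineage sorting.  It does not model gene
duplication/loss along the gene tree, hybridization, migration, or
non-ultrametric species trees; passing rates on these data say nothing
about such processes, nor about real alignments (no sequence evolution
or reconstruction error is simulated — triplet sets are read off the
true simulated tree).

## Experiments (`multriplet.evaluate`, `scripts/acceptance.py`)

`run_experiment` loops simulate → extract all triplets → rebuild →
compare, recording duplication classes (D_l / D_e / D_g for fewer /
equal / more duplications than the source), `d_R`, `d'_R`, isomorphism,
and — in `mode="both"` — agreement with the exact solver (instances the
exact search refuses are counted and excluded from the agreement
denominator).  Runtimes are logged, never asserted.

The acceptance script reports two numbers at the package's chosen desk
scale: (t1) the share of 100 simulated datasets with 5–30 gene copies
and species counts uniform in 3..max(3, n/2) where the heuristic's
duplication count is at most the source tree's; (t2) the share of 50
small datasets (5–9 copies over 5–7 species) where the heuristic matches
the exact optimum.  Dataset seeds are `1000·(seed−1) + i`, so `--seed 1`
uses dataset seeds 1..100 and 1..50.

These simulations also exhibit the consistency-principle failure the
package exists to study: on the heavily duplicated t1 datasets the
smallest consistent tree essentially always has *fewer* duplications
than the true tree (`d'_R > 0` throughout), i.e. the triplet set plus
duplication minimality does not pin down the source MUL tree.

## Numerical and convention choices

* Child order is non-semantic; the canonical form sorts children by
  their recursive canonical string, and isomorphism is canonical-form
  equality.
* Leaf labels are case-sensitive opaque strings; surrounding whitespace
  is trimmed; branch lengths and internal labels in Newick input are
  discarded.
* Distances require identical taxa sets by default
  (`allow_union=True` relaxes this).
* All stochastic components consume a single integer seed;
  derived seeds stay below 2^31.

## Known limitations

* The exact solver's pruning keeps 5–7 label instances comfortable but
  the search is exponential; `max_dup = 3` means instances whose optimum
  needs more duplications are refused, not approximated.
* The greedy separator enumeration is not guaranteed to find a
  minimum-size separator on every graph (the size bound can block the
  path to a smaller one), although no counterexample has appeared in
  randomized testing against exact vertex connectivity.
* `d'_R` comparisons between a tree and a raw triplet multiset skip the
  taxa-set check when the multiset's universe cannot be inferred beyond
  the labels it mentions.
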