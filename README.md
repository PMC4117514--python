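# multriplet

Multi-labeled phylogenetic trees (MUL trees) from rooted triplets.

MUL trees are rooted phylogenetic trees in which several leaves may
carry the same taxon label — the standard representation when gene
copies from polyploid genomes (or parasite lineages sampled per host)
are relabeled by the species they belong to.  Given a set of rooted
triplets `xy|z` ("x and y are closer to each other than to z"), the
**SMRT problem** asks for a MUL tree on exactly the label set L,
consistent with every triplet, with the fewest leaf duplications
`dup(T) = n(T) − |M(T)|`.  The problem is NP-hard.

This package is for phylogeneticists and method developers who want to
build such trees and, more pointedly, to probe whether they *should*:
it bundles everything needed to test the consistency principle — feed a
reconstruction method data generated from a known tree and ask whether
the tree comes back.

* `multriplet.mtrt` — **MTRT**, a deterministic polynomial heuristic for
  SMRT extending Aho's BUILD recursion: when the auxiliary graph (edge
  {x, y} for every triplet `xy|z`) is disconnected it recurses on the
  components like BUILD; when it is connected it duplicates a
  minimum-size minimal vertex separator S onto both sides, choosing
  among separators by the score
  `w(S) = α·|t(S)|/max(1,|t|) + ||L1|−|L2||/|L′|` (α = 2 by default).
  Every input triplet is consistent with the output by construction.
* `multriplet.exact_oracle` — exhaustive smallest-MUL-tree search with
  hard pruning, exact within an explicit budget (≤ 7 labels, ≤ 3
  duplications by default); refuses rather than answers wrongly.
* `multriplet.triplets` — triplet encodings with occurrence
  multiplicities, and the distances `d_R` (half the set symmetric
  difference of triplet encodings) and `d′_R` (half the multiset
  symmetric difference).  `d′_R` is a pseudometric only: distinct trees
  at distance 0 exist.
* `multriplet.simulate` — coalescent MUL trees: Yule species tree,
  random gene-to-species assignment, msprime multispecies coalescent,
  gene leaves relabeled by species.
* `multriplet.evaluate` — the simulate → extract → rebuild → compare
  experiment harness.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from multriplet import (SimConfig, simulate_mul_tree, triplet_set,
                        mtrt_build, compare, trip, exact_smallest_multree)

# two conflicting triplets force one duplication
out = mtrt_build({trip("a","b","c"), trip("b","c","a")}, {"a","b","c"})
print(out.to_newick(), out.dup_count())
# ((a,b),(b,c)); 1        <- matches the exact optimum

# simulate a MUL tree (10 gene copies, 4 species), rebuild from triplets
tree, record = simulate_mul_tree(SimConfig(n_genes=10, n_species=4, seed=11))
print(tree.to_newick(), tree.dup_count())
# ((s3,(s3,(s3,(s2,s3)))),(s2,((s1,s1),(s4,s4)))); 6

rebuilt = mtrt_build(triplet_set(tree), tree.label_set())
print(rebuilt.to_newick(), rebuilt.dup_count())
# (((s1,s2),s4),(s2,s3)); 1

print(compare(tree, rebuilt))
# ComparisonRecord(dup_in=6, dup_out=1, dup_class='D_l', dR=0.5,
#                  dpR=25.5, isomorphic=False, runtime_s=0.0)
```

The rebuilt tree satisfies every triplet of the source with five fewer
duplications, yet it is a different tree (`d′_R = 25.5`): the triplet
set plus duplication minimality does not pin down the source MUL tree —
the consistency-principle failure this package is built to quantify.

A CLI mirrors the library:

```sh
multriplet simulate --n-genes 10 --n-species 4 --seed 11 \
    --out sim.nwk --emit-triplets trips.tsv
multriplet build --triplets trips.tsv --out mtrt.nwk
multriplet distance --a sim.nwk --b mtrt.nwk --multiset
multriplet experiment --n 50 --seed 1 --mode both --out results.csv
```

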