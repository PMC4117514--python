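"""Coalescent-style synthetic MUL trees.

The generator mirrors the standard gene-tree-in-species-tree protocol:

1. draw an ultrametric rooted binary species tree from a Yule (pure
   birth) process;
2. assign the gene copies to species uniformly at random, every species
   receiving at least one copy;
3. run the multispecies coalescent backward in time — within each
   species-tree branch the gene lineages present merge pairwise at rate
   pairs/theta, lineages are pooled at species divergences, and the
   ancestral population above the root forces a common ancestor;
4. relabel every gene leaf with the species it was sampled from.

Step 3 uses msprime with a demography built from the species tree; the
resulting gene tree, once relabeled, is a rooted binary MUL tree whose
leaf count is the number of gene copies and whose label set is the
species set — so its duplication count is n_genes − n_species by
construction.  All randomness flows from the single configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import msprime
import numpy as np

from .multree import MULTree, Node, join, leaf

__all__ = ["SimConfig", "SpeciesTree", "simulate_species_tree", "simulate_mul_tree"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated MUL tree.

    n_genes: number of gene copies (leaves of the MUL tree).
    n_species: number of species (distinct labels); 2 ≤ n_species ≤ n_genes.
    pop_size_theta: coalescent intensity — within a population each pair
        of lineages merges at rate 1/theta.
    speciation_rate: birth rate of the Yule species tree.
    """

    n_genes: int
    n_species: int
    pop_size_theta: float = 1.0
    speciation_rate: float = 1.0
    seed: int = 1

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.n_genes < self.n_species:
            raise ValueError("every species needs at least one gene copy")
        if self.pop_size_theta <= 0 or self.speciation_rate <= 0:
            raise ValueError("rates must be positive")
        if self.seed < 1:
            raise ValueError("seed must be a positive integer")


class _YNode:
    __slots__ = ("children", "height", "name")

    def __init__(self):
        self.children: list["_YNode"] = []
        self.height = 0.0  # time before present; leaves are at 0
        self.name: str | None = None


@dataclass
class SpeciesTree:
    """An ultrametric rooted binary species tree.

    ``newick`` carries branch lengths (time units) and is consumable by
    msprime; ``divergence`` maps each unordered species pair to the
    height of its most recent common ancestor.
    """

    newick: str
    names: list[str]
    divergence: dict[frozenset[str], float]
    root_height: float


def simulate_species_tree(
    n_species: int, speciation_rate: float = 1.0, seed: int = 1
) -> SpeciesTree:
    """Yule (pure birth) ultrametric species tree.

    Forward in time: starting from the root split (2 lineages), with k
    lineages the next split arrives after an Exp(k·rate) wait and hits a
    uniformly chosen lineage; after the n-th lineage appears a final
    Exp(n·rate) stub runs to the present.  Expected root depth is
    therefore Σ_{k=2..n} 1/(k·rate); the tree is deterministic for a
    fixed seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)

    root = _YNode()
    a, b = _YNode(), _YNode()
    root.children = [a, b]
    split_depth = {id(root): 0.0}  # time since the root split
    tips = [a, b]
    t = 0.0
    while len(tips) < n_species:
        t += rng.exponential(1.0 / (len(tips) * speciation_rate))
        i = int(rng.integers(len(tips)))
        v = tips[i]
        c1, c2 = _YNode(), _YNode()
        v.children = [c1, c2]
        split_depth[id(v)] = t
        tips[i] = c1
        tips.append(c2)
    total = t + rng.exponential(1.0 / (n_species * speciation_rate))

    # convert split depths to heights above the present and name the tips
    names: list[str] = []

    def finish(v: _YNode) -> None:
        if v.children:
            v.height = total - split_depth[id(v)]
            for c in v.children:
                finish(c)
        else:
            v.height = 0.0
            v.name = f"s{len(names) + 1}"
            names.append(v.name)

    finish(root)

    divergence: dict[frozenset[str], float] = {}

    def collect(v: _YNode) -> list[str]:
        if not v.children:
            return [v.name]
        sides = [collect(c) for c in v.children]
        for x in sides[0]:
            for y in sides[1]:
                divergence[frozenset((x, y))] = v.height
        return sides[0] + sides[1]

    collect(root)

    def newick(v: _YNode, parent_height: float) -> str:
        bl = parent_height - v.height
        if not v.children:
            return f"{v.name}:{bl:.10f}"
        inner = ",".join(newick(c, v.height) for c in v.children)
        return f"({inner}):{bl:.10f}"

    nwk = newick(root, root.height)
    # strip the root's zero-length branch
    nwk = nwk.rsplit(":", 1)[0] + ";"
    return SpeciesTree(
        newick=nwk, names=names, divergence=divergence, root_height=root.height
    )


def simulate_mul_tree(cfg: SimConfig) -> tuple[MULTree, dict[str, Any]]:
    """One synthetic MUL tree plus a provenance record.

    Returns ``(tree, record)`` where the record carries everything needed
    to audit the draw: the species tree (newick, divergence times), the
    gene-to-species assignment, and for every coalescence in the gene
    tree its time and the species below each of its two children.
    """
    rng = np.random.default_rng(cfg.seed)
    sp = simulate_species_tree(cfg.n_species, cfg.speciation_rate, int(rng.integers(1, 2**31)))

    # every species gets one copy; the surplus is assigned uniformly
    counts = {name: 1 for name in sp.names}
    for i in rng.integers(cfg.n_species, size=cfg.n_genes - cfg.n_species):
        counts[sp.names[int(i)]] += 1

    # with ploidy 1 a lineage pair in a population of size N merges at
    # rate 1/N, so N = theta gives the stated pairs/theta intensity
    demography = msprime.Demography.from_species_tree(
        sp.newick, initial_size=cfg.pop_size_theta
    )
    ts = msprime.sim_ancestry(
        samples={name: counts[name] for name in sp.names},
        demography=demography,
        ploidy=1,
        random_seed=int(rng.integers(1, 2**31)),
    )
    gtree = ts.first()
    pop_name = {p.id: p.metadata["name"] for p in ts.populations()}
    sample_species = {
        u: pop_name[ts.node(u).population] for u in ts.samples()
    }

    coal_events: list[dict[str, Any]] = []

    def convert(u: int) -> tuple[Node, list[str]]:
        ch = gtree.children(u)
        if not ch:
            sp_name = sample_species[u]
            return leaf(sp_name), [sp_name]
        assert len(ch) == 2, "continuous-time coalescent trees are binary"
        n1, s1 = convert(ch[0])
        n2, s2 = convert(ch[1])
        coal_events.append(
            {"time": gtree.time(u), "left_species": sorted(s1), "right_species": sorted(s2)}
        )
        return join(n1, n2), s1 + s2

    root_node, _ = convert(gtree.root)
    tree = MULTree(root_node)

    record = {
        "config": cfg,
        "species_newick": sp.newick,
        "species_names": sp.names,
        "species_divergence": sp.divergence,
        "species_root_height": sp.root_height,
        "assignment": counts,
        "coalescences": coal_events,
    }
    return tree, record
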