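"""Shared fixtures and independent oracles.

The brute-force routines here deliberately re-derive quantities from
first principles (explicit LCA over all occurrence triples) so that the
package's optimized per-node counting is checked against an independent
route.
"""

from __future__ import annotations

import numpy as np
import pytest

from multriplet.multree import MULTree, Node, join, leaf
from multriplet.triplets import Triplet


# ---------------------------------------------------------------------
# brute-force triplet oracle


def _parent_map(tree: MULTree) -> dict[int, Node | None]:
    parents: dict[int, Node | None] = {id(tree.root): None}
    stack = [tree.root]
    while stack:
        v = stack.pop()
        for c in v.children:
            parents[id(c)] = v
            stack.append(c)
    return parents


def _ancestors(node: Node, parents) -> list[Node]:
    out = [node]
    while parents[id(node)] is not None:
        node = parents[id(node)]
        out.append(node)
    return out


def _lca(u: Node, v: Node, parents) -> Node:
    anc = {id(a) for a in _ancestors(u, parents)}
    for a in _ancestors(v, parents):
        if id(a) in anc:
            return a
    raise AssertionError("nodes share no ancestor")


def brute_force_multiplicity(t: Triplet, tree: MULTree) -> int:
    """Count occurrence triples (x_i, y_j, z_k) embedding the triplet,
    by explicit LCA comparison over every combination."""
    parents = _parent_map(tree)
    x, y = t.cherry
    z = t.outgroup
    leaves = tree.leaves()
    xs = [v for v in leaves if v.label == x]
    ys = [v for v in leaves if v.label == y]
    zs = [v for v in leaves if v.label == z]
    count = 0
    for xi in xs:
        for yj in ys:
            pair_lca = _lca(xi, yj, parents)
            pair_anc = {id(a) for a in _ancestors(pair_lca, parents)}
            for zk in zs:
                top = _lca(pair_lca, zk, parents)
                if id(top) in pair_anc and top is not pair_lca:
                    count += 1
    return count


def brute_force_consistent(t: Triplet, tree: MULTree) -> bool:
    return brute_force_multiplicity(t, tree) > 0


# ---------------------------------------------------------------------
# random tree generators


def random_binary_tree(labels: list[str], rng: np.random.Generator) -> MULTree:
    """Uniform-ish random rooted binary tree over the given leaf labels
    (labels may repeat), built by random pair joins."""
    nodes = [leaf(lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(join(a, b))
    return MULTree(nodes[0])


def random_mul_labels(
    rng: np.random.Generator, n_leaves: int, n_labels: int
) -> list[str]:
    """A leaf-label multiset with every label present at least once."""
    n_labels = min(n_labels, n_leaves)
    base = [f"s{i}" for i in range(n_labels)]
    extra = [base[int(k)] for k in rng.integers(n_labels, size=n_leaves - n_labels)]
    return base + extra


def random_triplet_set(
    rng: np.random.Generator, labels: list[str], n_triplets: int
) -> set[Triplet]:
    out: set[Triplet] = set()
    for _ in range(n_triplets):
        x, y, z = rng.choice(len(labels), size=3, replace=False)
        out.add(Triplet.make(labels[int(x)], labels[int(y)], labels[int(z)]))
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
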