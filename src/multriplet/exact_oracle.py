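"""Exact smallest-MUL-tree search by exhaustive enumeration.

The SMRT problem is NP-hard, so an exact answer is only feasible for
small label sets.  This module enumerates, for increasing duplication
count d = 0, 1, …, every leaf multiset over the label set with d extra
copies and every rooted binary tree shape over that multiset, and returns
the first tree consistent with all input triplets.  The result provably
minimizes the number of duplications among trees within the search
budget; if the budget is exhausted an explicit error is raised, never a
wrong answer.

Trees are grown leaf by leaf (each insertion subdivides an existing
edge), which allows hard pruning: inserting further leaves never changes
the relative topology of leaves already placed, so once every copy of a
triplet's three labels is present the triplet's consistency is decided —
branches that already violate a triplet are cut immediately.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator

from .multree import MULTree, Node, join, leaf
from .triplets import Triplet, is_consistent

__all__ = [
    "SearchBudget",
    "BudgetExceededError",
    "n_tree_shapes",
    "enumerate_multrees",
    "exact_smallest_multree",
]


class BudgetExceededError(RuntimeError):
    """The instance is too large for exhaustive search under the budget."""


@dataclass(frozen=True)
class SearchBudget:
    """Limits keeping the exhaustive search feasible.

    max_labels: largest label set accepted.
    max_dup: largest number of extra leaf copies tried.
    max_shapes: cap on (2m−3)!! for full-shape enumeration.
    max_steps: cap on leaf-insertion steps in the pruned search.
    """

    max_labels: int = 7
    max_dup: int = 3
    max_shapes: int = 2_000_000
    max_steps: int = 20_000_000

    def __post_init__(self):
        if self.max_labels < 1 or self.max_dup < 0:
            raise ValueError("budget fields must be positive")


def n_tree_shapes(m: int) -> int:
    """(2m−3)!!: the number of rooted binary tree shapes on m distinct leaves."""
    if m < 1:
        raise ValueError("need at least one leaf")
    out = 1
    for k in range(3, 2 * m - 2, 2):
        out *= k
    return out


# ---------------------------------------------------------------------
# enumeration of all MUL trees over a leaf multiset
#
# Internal representation during search: a leaf is its label string, an
# internal node is a 2-tuple of subtrees.  Cheap to copy and hash.


def _canon(t) -> str:
    if isinstance(t, str):
        return t
    a, b = _canon(t[0]), _canon(t[1])
    if b < a:
        a, b = b, a
    return f"({a},{b})"


def _insertions(t, lab: str) -> Iterator:
    """All trees obtained by attaching ``lab`` onto an edge of t (or above
    the root)."""
    yield (t, lab)
    if not isinstance(t, str):
        for sub in _insertions(t[0], lab):
            yield (sub, t[1])
        for sub in _insertions(t[1], lab):
            yield (t[0], sub)


def _to_multree(t) -> MULTree:
    def conv(u) -> Node:
        if isinstance(u, str):
            return leaf(u)
        return join(conv(u[0]), conv(u[1]))

    return MULTree(conv(t))


def enumerate_multrees(
    leaf_labels: Iterable[str], budget: SearchBudget | None = None
) -> Iterator[MULTree]:
    """Yield every rooted binary MUL tree over the leaf multiset, exactly
    once up to isomorphism (canonical-form deduplication)."""
    budget = budget or SearchBudget()
    labels = sorted(leaf_labels)
    if not labels:
        raise ValueError("empty leaf multiset")
    if n_tree_shapes(len(labels)) > budget.max_shapes:
        raise BudgetExceededError(
            f"{len(labels)} leaves gives {n_tree_shapes(len(labels))} shapes, "
            f"over the cap of {budget.max_shapes}"
        )
    trees = [labels[0]]
    for lab in labels[1:]:
        seen: set[str] = set()
        nxt = []
        for t in trees:
            for t2 in _insertions(t, lab):
                c = _canon(t2)
                if c not in seen:
                    seen.add(c)
                    nxt.append(t2)
        trees = nxt
    for t in trees:
        yield _to_multree(t)


# ---------------------------------------------------------------------
# pruned exact search


def exact_smallest_multree(
    triplets,
    labels,
    budget: SearchBudget | None = None,
) -> MULTree:
    """Smallest MUL tree on exactly ``labels`` consistent with all triplets.

    Searches duplication levels d = 0 … budget.max_dup in order; within a
    level, leaf multisets and insertion positions are explored in a fixed
    deterministic order and the first consistent tree found is returned,
    so results are reproducible.  Raises :class:`BudgetExceededError`
    when no consistent tree exists within the budget.
    """
    budget = budget or SearchBudget()
    labs = sorted(set(labels))
    trips = frozenset(triplets)
    for t in trips:
        if not t.labels <= set(labs):
            raise ValueError(f"triplet {t} uses labels outside the label set")
    if len(labs) > budget.max_labels:
        raise BudgetExceededError(
            f"{len(labs)} labels exceeds budget.max_labels={budget.max_labels}"
        )
    if len(labs) == 1:
        if trips:
            raise ValueError("triplets over a single label are impossible")
        return MULTree(leaf(labs[0]))

    steps = [0]
    for d in range(budget.max_dup + 1):
        for extra in itertools.combinations_with_replacement(labs, d):
            seq = sorted(labs + list(extra))
            found = _search(seq, trips, steps, budget.max_steps)
            if found is not None:
                tree = _to_multree(found)
                assert all(is_consistent(t, tree) for t in trips)
                return tree
            if steps[0] > budget.max_steps:
                raise BudgetExceededError(
                    f"step cap {budget.max_steps} hit before the search completed"
                )
    raise BudgetExceededError(
        f"no consistent tree with at most {budget.max_dup} duplications"
    )


def _search(seq: list[str], trips: frozenset[Triplet], steps: list[int], cap: int):
    """DFS over leaf-insertion orders for the sorted leaf sequence ``seq``.

    A triplet becomes checkable at position i when all copies of its
    three labels lie within seq[:i+1]; each is checked exactly once, at
    the first such i, and failing branches are pruned.
    """
    last_pos = {lab: i for i, lab in enumerate(seq)}
    checks: list[list[Triplet]] = [[] for _ in seq]
    for t in trips:
        checks[max(last_pos[lab] for lab in t.labels)].append(t)

    def consistent_here(tree, t: Triplet) -> bool:
        x, y = t.cherry
        z = t.outgroup

        def count(u, lab: str) -> int:
            if isinstance(u, str):
                return 1 if u == lab else 0
            return count(u[0], lab) + count(u[1], lab)

        ztot = count(tree, z)

        def walk(u) -> tuple[int, int, int, bool]:
            # returns (x, y, z counts in subtree, found)
            if isinstance(u, str):
                return (u == x, u == y, u == z, False)
            xl, yl, zl, fl = walk(u[0])
            if fl:
                return (0, 0, 0, True)
            xr, yr, zr, fr = walk(u[1])
            if fr:
                return (0, 0, 0, True)
            pairs = xl * yr + xr * yl
            if pairs and ztot - (zl + zr) > 0:
                return (0, 0, 0, True)
            return (xl + xr, yl + yr, zl + zr, False)

        return walk(tree)[3]

    def dfs(tree, i: int):
        if i == len(seq):
            return tree
        lab = seq[i]
        for t2 in _insertions(tree, lab):
            steps[0] += 1
            if steps[0] > cap:
                return None
            if all(consistent_here(t2, t) for t in checks[i]):
                r = dfs(t2, i + 1)
                if r is not None:
                    return r
        return None

    return dfs(seq[0], 1)
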