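"""MTRT: a top-down heuristic for the smallest-MUL-tree-from-triplets problem.

Given a set of rooted triplets over a label set L, the goal (the SMRT
problem, NP-hard) is a rooted binary MUL tree on exactly L that is
consistent with every triplet and has as few leaf duplications as
possible.  MTRT generalizes the classic Aho et al. BUILD recursion:

* Build the auxiliary graph on the current labels, with an edge {x, y}
  for every triplet xy|z.
* If the graph is disconnected, group its components into two sides and
  recurse on each side with the induced triplets — exactly BUILD, no
  duplication introduced.
* If the graph is connected, BUILD would fail; MTRT instead picks a
  minimal vertex separator S, duplicates the labels of S onto both
  sides, and recurses.  Triplets wholly inside S are dropped: because S
  appears on both sides of the new root, any such triplet (and any
  triplet whose cherry sits wholly in one side with its outgroup on the
  other) is automatically consistent with the assembled tree.

Candidate separators come from a greedy variant of the Berry–Bordat
AllMinSep enumeration, and among minimum-size separators the one with the
lowest score ``w`` is chosen, where ``w`` trades off the fraction of
triplets trapped inside the separator (weighted by ``alpha``, default 2)
against the imbalance of the two sides.

Every input triplet is consistent with the output tree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .multree import MULTree, Node, join, leaf
from .triplets import Triplet, induce, is_consistent

__all__ = [
    "build_aux_graph",
    "greedy_min_separators",
    "partition_components",
    "score_separator",
    "mtrt_build",
    "MTRTConfig",
]


@dataclass(frozen=True)
class MTRTConfig:
    """Tunables of the heuristic.

    alpha: weight of the triplets-inside-separator term of the separator
        score relative to the balance term.
    """

    alpha: float = 2.0


def build_aux_graph(triplets: set[Triplet] | frozenset[Triplet], labels) -> nx.Graph:
    """Auxiliary (Aho) graph: vertices = labels, edge {x,y} iff some xy|z."""
    lab = set(labels)
    g = nx.Graph()
    g.add_nodes_from(lab)
    for t in triplets:
        if not t.labels <= lab:
            raise ValueError(f"triplet {t} uses labels outside the given label set")
        g.add_edge(*t.cherry)
    return g


def greedy_min_separators(g: nx.Graph) -> list[frozenset[str]]:
    """Minimum-size minimal vertex separators found by a greedy enumeration.

    The full Berry–Bordat scheme seeds with the minimal separators close
    to each vertex (the neighborhoods of the components of G − N[v]) and
    then repeatedly expands every discovered separator S by each of its
    vertices x, taking neighborhoods of the components of G − (S ∪ N(x)).
    Enumerating everything can be exponential, so expansion here is
    greedy: a generated separator is kept only if its size does not
    exceed k, the smallest size seen so far (k is lowered whenever a
    smaller separator appears).  The returned list holds the distinct
    separators of the final minimum size, sorted; it is empty exactly
    when the graph is complete.
    """
    if not nx.is_connected(g):
        raise ValueError("auxiliary graph is disconnected; branch on components instead")
    n = g.number_of_nodes()
    if n < 3:
        return []

    found: set[frozenset[str]] = set()
    queue: list[frozenset[str]] = []

    def neighborhood_separators(removed: set[str]) -> list[frozenset[str]]:
        rest = g.subgraph(set(g.nodes) - removed)
        seps = []
        for comp in nx.connected_components(rest):
            border = frozenset(
                nb for u in comp for nb in g.neighbors(u) if nb not in comp
            )
            if border:
                seps.append(border)
        return seps

    # initial generation: one batch per vertex
    for v in sorted(g.nodes):
        closed = set(g.neighbors(v)) | {v}
        for s in neighborhood_separators(closed):
            if s not in found:
                found.add(s)
                queue.append(s)
    if not found:
        return []  # complete graph: no vertex separator exists

    k = min(len(s) for s in found)
    # greedy expansion, bounded by the current best size k
    i = 0
    while i < len(queue):
        s = queue[i]
        i += 1
        for x in sorted(s):
            for s2 in neighborhood_separators(set(s) | set(g.neighbors(x)) | {x}):
                if len(s2) <= k and s2 not in found:
                    found.add(s2)
                    queue.append(s2)
                    k = min(k, len(s2))
    return sorted((s for s in found if len(s) == k), key=sorted)


def partition_components(
    components: list[set[str]] | list[frozenset[str]],
) -> tuple[set[str], set[str]]:
    """Group ≥2 label components into two non-empty sides.

    Greedy balanced partition: components are taken by decreasing size
    (ties by lexicographically smallest member list) and each is assigned
    to the currently smaller side, ties going to the first side.
    """
    comps = sorted(components, key=lambda c: (-len(c), sorted(c)))
    if len(comps) < 2:
        raise ValueError("need at least two components to partition")
    x1: set[str] = set()
    x2: set[str] = set()
    for c in comps:
        (x1 if len(x1) <= len(x2) else x2).update(c)
    return x1, x2


def score_separator(
    separator: frozenset[str],
    triplets: frozenset[Triplet] | set[Triplet],
    labels: frozenset[str] | set[str],
    alpha: float = 2.0,
) -> float:
    """Score w of a separator; lower is better.

    w = alpha * |t(S)| / max(1, |t|)  +  ||L1| − |L2|| / |L'|

    The first term penalizes triplets trapped wholly inside the separator
    (they are dropped and tend to force further duplications); the second
    rewards a balanced split, where L1 = X1 ∪ S and L2 = X2 ∪ S for the
    grouped components X1, X2 of the graph minus the separator.
    """
    g = build_aux_graph(induce(triplets, labels), labels)
    rest = g.subgraph(set(labels) - separator)
    comps = [set(c) for c in nx.connected_components(rest)]
    if len(comps) < 2:
        raise ValueError("separator does not disconnect the auxiliary graph")
    x1, x2 = partition_components(comps)
    l1 = x1 | set(separator)
    l2 = x2 | set(separator)
    inside = len(induce(triplets, separator))
    return alpha * inside / max(1, len(triplets)) + abs(len(l1) - len(l2)) / len(labels)


# ---------------------------------------------------------------------
# the main recursion


def mtrt_build(
    triplets,
    labels,
    config: MTRTConfig | None = None,
    *,
    check: bool = False,
) -> MULTree:
    """Build a MUL tree on exactly ``labels`` consistent with every triplet.

    ``triplets`` may be any iterable of :class:`Triplet` (a multiset is
    collapsed to its underlying set — only membership matters here).
    With ``check=True`` the consistency guarantee is re-verified on the
    output, triplet by triplet.
    """
    cfg = config or MTRTConfig()
    trips = frozenset(triplets)
    labs = frozenset(labels)
    if not labs:
        raise ValueError("label set is empty")
    for t in trips:
        if not t.labels <= labs:
            raise ValueError(f"triplet {t} uses labels outside the label set")
    tree = MULTree(_build(trips, labs, cfg))
    if check:
        bad = [t for t in trips if not is_consistent(t, tree)]
        if bad:  # pragma: no cover - construction guarantees consistency
            raise AssertionError(f"output inconsistent with {bad}")
    return tree


def _build(trips: frozenset[Triplet], labs: frozenset[str], cfg: MTRTConfig) -> Node:
    if len(labs) == 1:
        (x,) = labs
        return leaf(x)
    if len(labs) == 2:
        assert not trips, "a triplet needs three labels"
        a, b = sorted(labs)
        return join(leaf(a), leaf(b))
    if not trips:
        # Case 1: no constraints left; any tree works — use a
        # deterministic caterpillar over the sorted labels.
        return _caterpillar(sorted(labs))

    g = build_aux_graph(trips, labs)
    comps = [set(c) for c in nx.connected_components(g)]
    if len(comps) > 1:
        x1, x2 = partition_components(comps)
        t1, t2 = _split_triplets(trips, frozenset(x1), frozenset(x2))
        return join(_build(t1, frozenset(x1), cfg), _build(t2, frozenset(x2), cfg))

    seps = greedy_min_separators(g)
    if not seps:
        return _complete_graph_split(trips, labs, cfg)

    best = min(
        seps,
        key=lambda s: (score_separator(s, trips, labs, cfg.alpha), sorted(s)),
    )
    rest = g.subgraph(set(labs) - best)
    x1, x2 = partition_components([set(c) for c in nx.connected_components(rest)])
    l1 = frozenset(x1 | set(best))
    l2 = frozenset(x2 | set(best))
    t1, t2 = _split_triplets(trips, l1, l2)
    return join(_build(t1, l1, cfg), _build(t2, l2, cfg))


def _split_triplets(
    trips: frozenset[Triplet], l1: frozenset[str], l2: frozenset[str]
) -> tuple[frozenset[Triplet], frozenset[Triplet]]:
    """Assign triplets to the two sides of a root split with label sets
    l1 and l2 (overlapping in the duplicated separator labels).

    A triplet whose cherry lies wholly inside one side while its outgroup
    occurs on the other side is consistent with the assembled tree no
    matter how the sides are built — the cherry's lowest common ancestor
    sits strictly below the root, the outgroup's occurrence hangs off the
    other root child.  Such triplets are dropped (this covers, in
    particular, every triplet wholly inside the separator).  Each
    remaining triplet has all labels in exactly one side and is passed
    there.
    """
    t1 = []
    t2 = []
    for t in trips:
        cherry = frozenset(t.cherry)
        z = t.outgroup
        if (cherry <= l1 and z in l2) or (cherry <= l2 and z in l1):
            continue
        if t.labels <= l1:
            t1.append(t)
        else:
            assert t.labels <= l2, "triplet not contained in either side"
            t2.append(t)
    return frozenset(t1), frozenset(t2)


def _complete_graph_split(
    trips: frozenset[Triplet], labs: frozenset[str], cfg: MTRTConfig
) -> Node:
    """Fallback when the auxiliary graph is complete (no separator exists).

    A complete graph can still admit a consistent MUL tree through a
    single-label duplication: hang one leaf x directly off the root and
    recurse on the rest.  Every triplet with outgroup x then becomes
    automatically consistent (its cherry lies in the other root subtree,
    its outgroup is the new leaf) and is dropped, so the triplet set
    strictly shrinks.  x is the label that drops the most triplets (ties
    broken lexicographically); it is kept in the recursive label set only
    if remaining triplets still mention it, so the step costs at most one
    duplication.
    """
    by_outgroup: dict[str, int] = {}
    for t in trips:
        by_outgroup[t.outgroup] = by_outgroup.get(t.outgroup, 0) + 1
    x = min(by_outgroup, key=lambda z: (-by_outgroup[z], z))
    remaining = frozenset(t for t in trips if t.outgroup != x)
    rest_labels = set(labs) - {x}
    for t in remaining:
        rest_labels |= t.labels
    return join(_build(remaining, frozenset(rest_labels), cfg), leaf(x))


def _caterpillar(labels: list[str]) -> Node:
    node = leaf(labels[0])
    if len(labels) == 1:
        return node
    node = join(node, leaf(labels[1]))
    for lab in labels[2:]:
        node = join(node, leaf(lab))
    return node
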