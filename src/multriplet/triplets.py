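"""Rooted triplets, triplet encodings of MUL trees, and triplet distances.

A rooted triplet ``xy|z`` is a binary rooted tree on three distinct taxa
in which the cherry pair {x, y} is closer to each other than either is to
the outgroup z.  A triplet is *consistent* with a MUL tree T when some
choice of one leaf occurrence per label embeds the triplet: the lowest
common ancestor of the chosen x and y occurrences is a proper descendant
of the lowest common ancestor of all three.

Because labels repeat in a MUL tree, a triplet can be embedded several
times; the *triplet encoding multiset* mt(T) records, for every triplet,
its number of embedded occurrence triples.  Two distances are defined on
top of these encodings:

* ``dist_dR``  — half the set symmetric difference of the triplet sets;
* ``dist_dpR`` — half the multiset symmetric difference of the triplet
  encoding multisets (a pseudometric: distinct MUL trees at distance 0
  exist).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from .multree import MULTree, Node

TripletSet = frozenset
TripletMultiset = Counter


@dataclass(frozen=True, order=True)
class Triplet:
    """A rooted triplet xy|z on three distinct labels.

    ``cherry`` is stored sorted so that {x,y}|z and {y,x}|z compare equal.
    """

    cherry: tuple[str, str]
    outgroup: str

    @classmethod
    def make(cls, x: str, y: str, z: str) -> "Triplet":
        if len({x, y, z}) != 3:
            raise ValueError(f"triplet labels must be distinct: {x!r}, {y!r}, {z!r}")
        a, b = sorted((x, y))
        return cls((a, b), z)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset((*self.cherry, self.outgroup))

    def __str__(self) -> str:
        return f"{self.cherry[0]},{self.cherry[1]}|{self.outgroup}"


def trip(x: str, y: str, z: str) -> Triplet:
    """Shorthand constructor: ``trip('a','b','c')`` is the triplet ab|c."""
    return Triplet.make(x, y, z)


# ---------------------------------------------------------------------
# consistency and the triplet encoding


def is_consistent(t: Triplet, tree: MULTree) -> bool:
    """True iff t is an embedded subtree of the MUL tree.

    Labels of t absent from the tree simply make this False.
    """
    x, y = t.cherry
    z = t.outgroup
    counts, totals = _subtree_label_counts(tree)
    if not (totals.get(x) and totals.get(y) and totals.get(z)):
        return False
    for v in tree.internal_nodes():
        left, right = v.children
        cl, cr = counts[id(left)], counts[id(right)]
        pairs = cl.get(x, 0) * cr.get(y, 0) + cl.get(y, 0) * cr.get(x, 0)
        if pairs and totals[z] - counts[id(v)].get(z, 0) > 0:
            return True
    return False


def triplet_multiset(tree: MULTree) -> TripletMultiset:
    """The triplet encoding multiset mt(T).

    The multiplicity of xy|z is the number of occurrence triples
    (x_i, y_j, z_k) with lca(x_i, y_j) a proper descendant of
    lca(x_i, y_j, z_k).  Counted per internal node: pairs whose lca is
    exactly that node, times the z occurrences outside its subtree.
    """
    counts, totals = _subtree_label_counts(tree)
    out: TripletMultiset = Counter()
    for v in tree.internal_nodes():
        left, right = v.children
        cl, cr = counts[id(left)], counts[id(right)]
        cv = counts[id(v)]
        for x, nx in cl.items():
            for y, ny in cr.items():
                if x == y:
                    continue
                pairs = nx * ny
                for z, nz in totals.items():
                    if z == x or z == y:
                        continue
                    outside = nz - cv.get(z, 0)
                    if outside:
                        out[Triplet.make(x, y, z)] += pairs * outside
    return out


def triplet_set(tree: MULTree) -> TripletSet:
    """t(T): the set of all triplets consistent with the tree."""
    return frozenset(triplet_multiset(tree))


def triplet_multiplicity(t: Triplet, tree: MULTree) -> int:
    """Number of embedded occurrence triples of t in the tree."""
    x, y = t.cherry
    z = t.outgroup
    counts, totals = _subtree_label_counts(tree)
    if not (totals.get(x) and totals.get(y) and totals.get(z)):
        return 0
    total = 0
    for v in tree.internal_nodes():
        left, right = v.children
        cl, cr = counts[id(left)], counts[id(right)]
        pairs = cl.get(x, 0) * cr.get(y, 0) + cl.get(y, 0) * cr.get(x, 0)
        if pairs:
            total += pairs * (totals[z] - counts[id(v)].get(z, 0))
    return total


def _subtree_label_counts(tree: MULTree) -> tuple[dict[int, Counter], Counter]:
    counts: dict[int, Counter] = {}
    for v in tree.postorder():
        if v.is_leaf:
            counts[id(v)] = Counter({v.label: 1})
        else:
            c = Counter()
            for ch in v.children:
                c.update(counts[id(ch)])
            counts[id(v)] = c
    return counts, counts[id(tree.root)]


# ---------------------------------------------------------------------
# induced sets and multiset algebra


def induce(triplets: Iterable[Triplet], labels: Iterable[str]) -> TripletSet:
    """t(L'): the triplets whose three labels all lie inside L'."""
    lab = frozenset(labels)
    return frozenset(t for t in triplets if t.labels <= lab)


def multiset_symdiff(m1: TripletMultiset, m2: TripletMultiset) -> TripletMultiset:
    """Multiset symmetric difference: multiplicity |m1(x) − m2(x)| per element."""
    out: TripletMultiset = Counter()
    for t in set(m1) | set(m2):
        d = abs(m1.get(t, 0) - m2.get(t, 0))
        if d:
            out[t] = d
    return out


def multiset_size(m: TripletMultiset) -> int:
    return sum(m.values())


# ---------------------------------------------------------------------
# distances


class TaxaMismatchError(ValueError):
    """The two objects are not over the same taxa set."""

    def __init__(self, only_first: set[str], only_second: set[str]):
        super().__init__(
            "taxa sets differ: only in first "
            f"{sorted(only_first)}, only in second {sorted(only_second)}"
        )
        self.only_first = only_first
        self.only_second = only_second


def _check_taxa(l1: frozenset[str], l2: frozenset[str], allow_union: bool) -> None:
    if allow_union or l1 == l2:
        return
    raise TaxaMismatchError(set(l1 - l2), set(l2 - l1))


def dist_dR(t1: MULTree, t2: MULTree, *, allow_union: bool = False) -> float:
    """Rooted triplet distance: |t(T1) Δ t(T2)| / 2 (set symmetric difference)."""
    _check_taxa(t1.label_set(), t2.label_set(), allow_union)
    return len(triplet_set(t1) ^ triplet_set(t2)) / 2


TreeOrMultiset = Union[MULTree, TripletMultiset]


def dist_dpR(a: TreeOrMultiset, b: TreeOrMultiset, *, allow_union: bool = False) -> float:
    """Multiset triplet distance: |mt(·) Δ mt(·)| / 2.

    Either argument may be a MUL tree (converted through its triplet
    encoding multiset) or a triplet multiset directly.
    """
    ma, la = _as_multiset(a)
    mb, lb = _as_multiset(b)
    if la is not None and lb is not None:
        _check_taxa(la, lb, allow_union)
    return multiset_size(multiset_symdiff(ma, mb)) / 2


def _as_multiset(x: TreeOrMultiset) -> tuple[TripletMultiset, frozenset[str] | None]:
    if isinstance(x, MULTree):
        return triplet_multiset(x), x.label_set()
    if isinstance(x, Counter):
        labels: set[str] = set()
        for t in x:
            labels |= t.labels
        return x, frozenset(labels)
    raise TypeError(f"expected MULTree or triplet multiset, got {type(x).__name__}")


# ---------------------------------------------------------------------
# TSV I/O
#
# One triplet per line: "x<TAB>y<TAB>z" meaning xy|z, with an optional
# fourth integer column giving the multiplicity (default 1).  Lines
# starting with '#' are comments.  The writer sorts lexicographically.


def read_triplets_tsv(path: str | Path) -> TripletMultiset:
    out: TripletMultiset = Counter()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (3, 4):
            raise ValueError(
                f"{path}:{lineno}: expected 3 or 4 tab-separated fields, got {len(fields)}"
            )
        x, y, z = (f.strip() for f in fields[:3])
        mult = 1
        if len(fields) == 4:
            mult = int(fields[3])
            if mult < 1:
                raise ValueError(f"{path}:{lineno}: multiplicity must be positive")
        out[Triplet.make(x, y, z)] += mult
    return out


def write_triplets_tsv(
    path: str | Path, triplets: TripletMultiset | Iterable[Triplet], *, multiset: bool = True
) -> None:
    if not isinstance(triplets, Counter):
        triplets = Counter(dict.fromkeys(triplets, 1))
    lines = []
    for t in sorted(triplets):
        m = triplets[t]
        if multiset and m != 1:
            lines.append(f"{t.cherry[0]}\t{t.cherry[1]}\t{t.outgroup}\t{m}")
        else:
            lines.append(f"{t.cherry[0]}\t{t.cherry[1]}\t{t.outgroup}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
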