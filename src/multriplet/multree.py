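"""Rooted binary multi-labeled phylogenetic trees (MUL trees).

A MUL tree is a rooted phylogenetic tree in which several leaves may carry
the same taxon label — the usual situation when gene copies from a
polyploid genome, or multiple parasite lineages from one host, are
relabeled by the species they belong to.  This module holds the data
model, Newick I/O with repeated leaf labels, duplication counting, and a
canonical form used for isomorphism tests.

Only the topology is modelled.  Branch lengths and internal-node labels in
Newick input are accepted and discarded; child order is non-semantic.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterator


class NewickError(ValueError):
    """Malformed Newick input.  ``offset`` is the 0-based character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class Node:
    """A node of a MUL tree: either a labeled leaf or an internal node
    with exactly two children."""

    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children: tuple["Node", ...] = ()):
        self.label = label
        self.children = children

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r})" if self.is_leaf else f"Node({self.children!r})"


def leaf(label: str) -> Node:
    return Node(label=label)


def join(left: Node, right: Node) -> Node:
    """New root with the two given subtrees as children."""
    return Node(children=(left, right))


class MULTree:
    """A rooted binary MUL tree.

    Invariants: every internal node has exactly two children; every leaf
    carries a non-empty label; labels may repeat across leaves.
    """

    __slots__ = ("root", "_canon")

    def __init__(self, root: Node):
        _validate(root)
        self.root = root
        self._canon: str | None = None

    # -- constructors -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, *, resolve_polytomies: bool = False) -> "MULTree":
        return parse_newick(text, resolve_polytomies=resolve_polytomies)

    # -- basic accessors ----------------------------------------------

    def leaves(self) -> list[Node]:
        return [v for v in self.postorder() if v.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [v.label for v in self.leaves()]

    def label_multiset(self) -> Counter:
        return Counter(self.leaf_labels())

    def label_set(self) -> frozenset[str]:
        """M(T): the set of distinct leaf labels."""
        return frozenset(self.leaf_labels())

    @property
    def n_leaves(self) -> int:
        """n(T): the number of leaves."""
        return len(self.leaves())

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            v, expanded = stack.pop()
            if expanded or v.is_leaf:
                yield v
            else:
                stack.append((v, True))
                for c in reversed(v.children):
                    stack.append((c, False))

    def internal_nodes(self) -> list[Node]:
        return [v for v in self.postorder() if not v.is_leaf]

    # -- derived quantities -------------------------------------------

    def dup_count(self) -> int:
        """dup(T) = n(T) − |M(T)|, the total number of leaf duplications."""
        labels = self.leaf_labels()
        return len(labels) - len(set(labels))

    def canonical_form(self) -> str:
        if self._canon is None:
            self._canon = _canonical(self.root)
        return self._canon

    def is_isomorphic(self, other: "MULTree") -> bool:
        return self.canonical_form() == other.canonical_form()

    def to_newick(self) -> str:
        return _write(self.root) + ";"

    def __repr__(self) -> str:
        return f"MULTree({self.to_newick()!r})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MULTree):
            return NotImplemented
        return self.canonical_form() == other.canonical_form()

    def __hash__(self) -> int:
        return hash(self.canonical_form())


# ---------------------------------------------------------------------
# module-level functional interface


def dup_count(tree: MULTree) -> int:
    return tree.dup_count()


def canonical_form(tree: MULTree) -> str:
    return tree.canonical_form()


def is_isomorphic(t1: MULTree, t2: MULTree) -> bool:
    """Equality as rooted leaf-labeled trees, ignoring child order."""
    return t1.is_isomorphic(t2)


def write_newick(tree: MULTree) -> str:
    return tree.to_newick()


def _validate(node: Node) -> None:
    stack = [node]
    while stack:
        v = stack.pop()
        if v.is_leaf:
            if not v.label:
                raise ValueError("leaf with empty label")
        else:
            if len(v.children) != 2:
                raise ValueError(
                    f"internal node with {len(v.children)} children; MUL trees are binary"
                )
            stack.extend(v.children)


def _canonical(node: Node) -> str:
    if node.is_leaf:
        return node.label
    return "(" + ",".join(sorted(_canonical(c) for c in node.children)) + ")"


def _write(node: Node) -> str:
    if node.is_leaf:
        return node.label
    return "(" + ",".join(_write(c) for c in node.children) + ")"


# ---------------------------------------------------------------------
# Newick parsing

_RESERVED = set("(),;:[]")


def parse_newick(text: str, *, resolve_polytomies: bool = False) -> MULTree:
    """Parse a rooted Newick string into a :class:`MULTree`.

    Leaf labels need not be unique.  Branch lengths and internal-node
    labels are discarded.  Non-binary nodes are rejected unless
    ``resolve_polytomies`` is set, in which case they are resolved into a
    left-deep ladder (an arbitrary but deterministic refinement).
    """
    parser = _Parser(text, resolve_polytomies)
    return parser.parse()


class _Parser:
    def __init__(self, text: str, resolve_polytomies: bool):
        self.text = text
        self.pos = 0
        self.resolve = resolve_polytomies

    def parse(self) -> MULTree:
        self._skip_ws()
        root = self._subtree()
        self._skip_ws()
        if self.pos >= len(self.text) or self.text[self.pos] != ";":
            raise NewickError("expected ';' terminating the tree", self.pos)
        self.pos += 1
        self._skip_ws()
        if self.pos != len(self.text):
            raise NewickError("trailing characters after ';'", self.pos)
        return MULTree(root)

    def _subtree(self) -> Node:
        self._skip_ws()
        if self.pos >= len(self.text):
            raise NewickError("unexpected end of input", self.pos)
        if self.text[self.pos] == "(":
            open_pos = self.pos
            self.pos += 1
            children = [self._subtree()]
            self._skip_ws()
            while self.pos < len(self.text) and self.text[self.pos] == ",":
                self.pos += 1
                children.append(self._subtree())
                self._skip_ws()
            if self.pos >= len(self.text) or self.text[self.pos] != ")":
                raise NewickError("unbalanced parentheses: missing ')'", self.pos)
            self.pos += 1
            self._discard_label_and_length(internal=True)
            if len(children) == 1:
                # unary nodes carry no information; collapse them
                return children[0]
            if len(children) > 2:
                if not self.resolve:
                    raise NewickError(
                        f"non-binary node with {len(children)} children", open_pos
                    )
                node = join(children[0], children[1])
                for extra in children[2:]:
                    node = join(node, extra)
                return node
            return join(children[0], children[1])
        label = self._leaf_label()
        self._discard_label_and_length(internal=False)
        return leaf(label)

    def _leaf_label(self) -> str:
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in _RESERVED:
            self.pos += 1
        label = self.text[start : self.pos].strip()
        if not label:
            raise NewickError("empty leaf label", start)
        return label

    def _discard_label_and_length(self, internal: bool) -> None:
        # optional internal-node label
        if internal:
            while self.pos < len(self.text) and self.text[self.pos] not in _RESERVED:
                self.pos += 1
        # optional branch length
        self._skip_ws()
        if self.pos < len(self.text) and self.text[self.pos] == ":":
            self.pos += 1
            start = self.pos
            while self.pos < len(self.text) and self.text[self.pos] not in _RESERVED:
                self.pos += 1
            try:
                float(self.text[start : self.pos].strip())
            except ValueError:
                raise NewickError("malformed branch length", start) from None

    def _skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1
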