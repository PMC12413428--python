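"""Canonical rooted binary tree shapes.

A *tree shape* is the isomorphism class of a rooted tree in which every
vertex has out-degree 0 or 2, with leaves unlabeled.  Shapes are the
universal input to every balance index and tree model in this package.

Shapes are interned: two structurally isomorphic trees are represented by
the same :class:`TreeShape` object, so isomorphism testing is an identity
(or key) comparison.  The canonical form orders the two children of every
internal vertex by (leaf count, canonical key), ascending.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from typing import Iterator

import dendropy

__all__ = [
    "TreeShape",
    "leaf",
    "join",
    "from_newick",
    "to_newick",
    "subtree_sizes",
    "count_labelings",
    "height",
]

_INTERN: dict[str, "TreeShape"] = {}


class TreeShape:
    """An interned, canonical, unlabeled rooted binary tree shape.

    Attributes
    ----------
    children : tuple
        Empty for a leaf, otherwise exactly two child shapes in canonical
        order (first child <= second child by (leaf_count, key)).
    leaf_count : int
        Number of leaves n; the *size* of the shape.
    key : str
        Canonical anonymous-leaf Newick string (without the trailing
        semicolon).  Equal keys <=> isomorphic shapes.
    """

    __slots__ = ("children", "leaf_count", "key")

    def __init__(self, children: tuple, leaf_count: int, key: str):
        self.children = children
        self.leaf_count = leaf_count
        self.key = key

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeShape(n={self.leaf_count}, {self.key!r})"

    def __hash__(self) -> int:
        return hash(self.key)

    def __eq__(self, other) -> bool:
        if isinstance(other, TreeShape):
            return self is other or self.key == other.key
        return NotImplemented

    def __lt__(self, other: "TreeShape") -> bool:
        return (self.leaf_count, self.key) < (other.leaf_count, other.key)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def internal_vertices(self) -> Iterator["TreeShape"]:
        """Iterate over the pending subtrees rooted at internal vertices.

        Each internal vertex v is represented by its pending subtree T_v;
        the multiset of their leaf counts is the subtree-size spectrum.
        """
        stack = [self]
        while stack:
            node = stack.pop()
            if node.children:
                yield node
                stack.extend(node.children)


def leaf() -> TreeShape:
    """The single-vertex shape (n = 1): the root is its only leaf."""
    t = _INTERN.get("")
    if t is None:
        t = _INTERN.setdefault("", TreeShape((), 1, ""))
    return t


def join(a: TreeShape, b: TreeShape) -> TreeShape:
    """Join two shapes under a new root, in canonical child order."""
    if (b.leaf_count, b.key) < (a.leaf_count, a.key):
        a, b = b, a
    key = f"({a.key},{b.key})"
    t = _INTERN.get(key)
    if t is None:
        t = _INTERN.setdefault(key, TreeShape((a, b), a.leaf_count + b.leaf_count, key))
    return t


_COMMENT_RE = re.compile(r"\[[^\]]*\]")


def from_newick(text: str) -> TreeShape:
    """Parse a Newick string into its canonical shape.

    Leaf labels, internal labels, branch lengths and comments are read and
    discarded; the result depends only on the topology.  Raises
    ``ValueError`` on syntax errors or if any node has out-degree 1 or >= 3.
    """
    stripped = _COMMENT_RE.sub("", text).strip()
    if not stripped.endswith(";"):
        stripped += ";"
    body = stripped[:-1].strip()
    if "(" not in body:
        # single-vertex tree: ";" or "label;" (possibly with a length)
        return leaf()
    tree = dendropy.Tree.get(data=stripped, schema="newick",
                             suppress_internal_node_taxa=True)

    def convert(node) -> TreeShape:
        kids = node.child_nodes()
        if not kids:
            return leaf()
        if len(kids) != 2:
            raise ValueError(
                f"non-binary tree: node with {len(kids)} children"
            )
        return join(convert(kids[0]), convert(kids[1]))

    return convert(tree.seed_node)


def to_newick(t: TreeShape) -> str:
    """Canonical anonymous-leaf Newick serialization (round-trip safe)."""
    return t.key + ";"


def subtree_sizes(t: TreeShape) -> Counter:
    """Multiset {n_v : v internal} of pending-subtree sizes.

    Has n - 1 elements (counted with multiplicity) for n >= 2 and is empty
    for the single-vertex shape; the maximum element is n and every
    element is >= 2.
    """
    return Counter(v.leaf_count for v in t.internal_vertices())


def count_labelings(t: TreeShape) -> int:
    """Number of phylogenetic X-trees (|X| = n, labeled leaves) with shape t.

    Equals n! / 2^s where s is the number of internal vertices whose two
    child subtrees are isomorphic (each such vertex halves the count by
    the label-swap symmetry).
    """
    s = sum(1 for v in t.internal_vertices() if v.children[0] is v.children[1])
    return math.factorial(t.leaf_count) // (2 ** s)


def height(t: TreeShape) -> int:
    """Maximum vertex depth; 0 for the single-vertex shape."""
    best = 0
    stack = [(t, 0)]
    while stack:
        node, d = stack.pop()
        if node.children:
            stack.extend((c, d + 1) for c in node.children)
        elif d > best:
            best = d
    return best
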