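"""Shared brute-force oracles over labeled trees.

Labeled rooted binary trees are represented as nested tuples with integer
leaf labels: a leaf is an int, an internal node a pair (left, right).
Every labeled tree on n leaves arises exactly once by inserting leaf n-1
above one of the 2(n-1)-1 nodes of a tree on n-1 leaves, which is how the
enumeration proceeds (and why there are (2n-3)!! of them).  These oracles
are deliberately independent of the package's shape machinery.
"""

from functools import lru_cache

from gfbtree.tree_core import TreeShape, join, leaf


def _insert_everywhere(t, label):
    yield (t, label)
    if isinstance(t, tuple):
        for sub in _insert_everywhere(t[0], label):
            yield (sub, t[1])
        for sub in _insert_everywhere(t[1], label):
            yield (t[0], sub)


@lru_cache(maxsize=None)
def labeled_trees(n: int) -> tuple:
    """All (2n-3)!! labeled rooted binary trees on leaves 0..n-1."""
    if n == 1:
        return (0,)
    if n == 2:
        return (((0, 1)),)
    out = []
    for t in labeled_trees(n - 1):
        out.extend(_insert_everywhere(t, n - 1))
    return tuple(out)


def shape_of(t) -> TreeShape:
    """Canonical shape of a labeled tree."""
    if isinstance(t, int):
        return leaf()
    return join(shape_of(t[0]), shape_of(t[1]))


def leafset(t) -> frozenset:
    if isinstance(t, int):
        return frozenset([t])
    return leafset(t[0]) | leafset(t[1])


def clusters(t) -> list:
    """All clusters (pending-subtree leaf sets) of a labeled tree,
    including singletons and the root cluster."""
    out = []

    def rec(node):
        if isinstance(node, int):
            s = frozenset([node])
        else:
            s = rec(node[0]) | rec(node[1])
        out.append(s)
        return s

    rec(t)
    return out
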