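"""Constructors for the named extremal tree shapes and exhaustive enumeration.

The central construction is the *greedy-from-the-bottom* (GFB) tree: start
from a forest of n single-vertex trees and repeatedly join two trees of
minimal size until one tree remains.  The GFB tree coincides with the
*complete* tree (fully balanced tree of the next lower power of two with
cherries attached left to right), and is the unique minimizer of a large
family of subtree-size based imbalance indices.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterator, Optional

from .tree_core import TreeShape, join, leaf

__all__ = [
    "caterpillar",
    "fully_balanced",
    "maximally_balanced",
    "gfb",
    "gfb_forests",
    "complete",
    "gfb_split_sizes",
    "enumerate_shapes",
    "ceil_log2",
]


def _require_positive(n: int) -> None:
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")


def ceil_log2(n: int) -> int:
    """Exact integer ceil(log2 n) without floating-point log."""
    _require_positive(n)
    return (n - 1).bit_length()


def caterpillar(n: int) -> TreeShape:
    """The caterpillar (pectinate) shape: at most one cherry, height n - 1."""
    _require_positive(n)
    t = leaf()
    for _ in range(n - 1):
        t = join(t, leaf())
    return t


def fully_balanced(h: int) -> TreeShape:
    """The fully balanced shape of height h: 2^h leaves, all at depth h."""
    if h < 0:
        raise ValueError(f"height must be nonnegative, got {h}")
    t = leaf()
    for _ in range(h):
        t = join(t, t)
    return t


def maximally_balanced(n: int) -> TreeShape:
    """The maximally balanced shape: every internal vertex u with children
    v, w satisfies |n_v - n_w| <= 1 (root split (ceil(n/2), floor(n/2)),
    recursively)."""
    _require_positive(n)
    if n == 1:
        return leaf()
    half = n // 2
    return join(maximally_balanced(n - half), maximally_balanced(half))


def gfb_forests(n: int, rng=None) -> Iterator[list[TreeShape]]:
    """Yield each intermediate forest of the greedy clustering run.

    The first forest is n single-vertex trees, the last is [gfb(n)].  Ties
    among minimal-size trees are broken by canonical order, or uniformly at
    random when ``rng`` (a ``random.Random``) is given -- the resulting
    tree is tie-break independent (a tested property, not an assumption).
    """
    _require_positive(n)
    forest = [leaf()] * n
    yield list(forest)
    while len(forest) > 1:
        if rng is None:
            forest.sort(key=lambda t: (t.leaf_count, t.key))
        else:
            forest.sort(key=lambda t: (t.leaf_count, rng.random()))
        merged = join(forest[0], forest[1])
        forest = forest[2:]
        forest.append(merged)
        yield list(forest)


def gfb(n: int, rng=None) -> TreeShape:
    """The greedy-from-the-bottom tree on n leaves."""
    for forest in gfb_forests(n, rng=rng):
        pass
    return forest[0]


def complete(n: int) -> TreeShape:
    """Fill's complete tree: the fully balanced tree on 2^floor(log2 n)
    leaves with n - 2^floor(log2 n) leaves replaced by cherries from left
    to right.  Equals gfb(n) for every n (a tested equivalence)."""
    _require_positive(n)
    h = n.bit_length() - 1  # floor(log2 n)
    d = n - (1 << h)  # number of leaves to replace by cherries

    def build(height: int, cherries: int) -> TreeShape:
        # fully balanced subtree of 2^height leaves whose leftmost
        # `cherries` leaves become cherries
        if height == 0:
            return join(leaf(), leaf()) if cherries else leaf()
        half = 1 << (height - 1)
        left = build(height - 1, min(cherries, half))
        right = build(height - 1, max(cherries - half, 0))
        return join(left, right)

    return build(h, d)


def gfb_split_sizes(n: int) -> tuple[int, int]:
    """Sizes (n_a, n_b), n_a >= n_b, of the maximal pending subtrees of
    gfb(n), by the closed-form case split on k_n = ceil(log2 n):
    the smaller side is the largest power of two <= n/2 when n sits in the
    lower half of (2^{k_n - 1}, 2^{k_n}], else the larger side is
    2^{k_n - 1}."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    k = ceil_log2(n)
    quarter = 1 << (k - 2) if k >= 2 else 0
    if k >= 2 and (1 << (k - 1)) < n <= 3 * quarter:
        return (n - quarter, quarter)
    return ((1 << (k - 1)), n - (1 << (k - 1)))


@lru_cache(maxsize=None)
def enumerate_shapes(n: int) -> tuple[TreeShape, ...]:
    """All distinct shapes on n leaves, deterministically ordered.

    Recursive enumeration over unordered root splits (a <= b, a + b = n);
    the equal-split case iterates over unordered shape pairs including
    equal pairs, so counts follow the Wedderburn-Etherington recursion.
    Practical up to n ~ 20.
    """
    _require_positive(n)
    if n == 1:
        return (leaf(),)
    out: list[TreeShape] = []
    for a in range(1, n // 2 + 1):
        b = n - a
        left_shapes = enumerate_shapes(a)
        right_shapes = enumerate_shapes(b)
        if a < b:
            out.extend(join(x, y) for x in left_shapes for y in right_shapes)
        else:  # a == b: unordered pairs with repetition
            for i, x in enumerate(left_shapes):
                out.extend(join(x, right_shapes[j])
                           for j in range(i, len(right_shapes)))
    out.sort(key=lambda t: t.key)
    return tuple(out)
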