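"""Closed-form formulas attached to the GFB tree.

The GFB tree's subtree-size spectrum a_n(i) -- the number of pending
subtrees of size i -- admits a non-recursive four-case formula, from which
pi_c of the GFB tree and the minimum values of the s-hat and Q-shape
statistics follow as simple products.  A second, independent direct
formula computes pi_c(gfb(n)) from the decomposition of the GFB tree as a
fully balanced tree with cherries attached; the two routes agree exactly
in rational arithmetic (a tested equivalence).

All products with integer c are evaluated exactly (Fraction/int), so the
pi_{-1} sequence 1, 1, 2, 3, 8, 15, 36, 63, 192, 405, ... is bit-exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Union

from .generators import ceil_log2

__all__ = [
    "SubtreeSizeCounts",
    "subtree_size_counts",
    "pi_c_gfb_via_counts",
    "pi_c_gfb_direct",
    "min_s_hat",
    "min_q",
    "gfb_value_sequence",
]

Real = Union[int, float]


@dataclass(frozen=True)
class SubtreeSizeCounts:
    """The map i -> a_n(i): multiplicity of size-i pending subtrees of gfb(n).

    Covers i = 1..n (a_n(1) = n counts the leaves, a_n(n) = 1 the root);
    the multiplicities over i >= 2 sum to n - 1, the number of internal
    vertices.
    """

    n: int
    counts: dict[int, int]

    def __getitem__(self, i: int) -> int:
        return self.counts.get(i, 0)


def subtree_size_counts(n: int) -> SubtreeSizeCounts:
    """a_n(i) for i = 1..n by the four-case closed form.

    With k_i = ceil(log2 i):

    * i a power of two and (n mod i = 0 or n mod i >= i/2):  floor(n/i)
    * i a power of two and 0 < n mod i < i/2:                floor(n/i) - 1
    * i not a power of two and (n - i) mod 2^(k_i - 1) = 0:  1
    * otherwise:                                             0
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    counts: dict[int, int] = {1: n}
    for i in range(2, n + 1):
        ki = ceil_log2(i)
        if i == 1 << ki:  # power of two
            r = n % i
            if r == 0 or r >= i // 2:
                a = n // i
            else:
                a = n // i - 1
        else:
            a = 1 if (n - i) % (1 << (ki - 1)) == 0 else 0
        if a:
            counts[i] = a
    return SubtreeSizeCounts(n=n, counts=counts)


def _exact_c(c: Real) -> bool:
    return isinstance(c, int) or (isinstance(c, float) and c.is_integer())


def pi_c_gfb_via_counts(n: int, c: Real) -> Real:
    """pi_c(gfb(n)) = prod_{i=2}^{n} (i + c)^{a_n(i)}.

    Exact (int) for integer c, float otherwise.
    """
    if c <= -2:
        raise ValueError(f"c must exceed -2, got {c}")
    a = subtree_size_counts(n)
    if _exact_c(c):
        ci = int(c)
        prod = 1
        for i, mult in a.counts.items():
            if i >= 2:
                prod *= (i + ci) ** mult
        return prod
    prod = 1.0
    for i, mult in a.counts.items():
        if i >= 2:
            prod *= (i + c) ** mult
    return prod


def _pi_c_fb(h: int, c: Real, exact: bool) -> Real:
    """pi_c of the fully balanced tree of height h:
    prod_{i=0}^{h-1} (2^{h-i} + c)^{2^i}."""
    prod: Real = 1 if exact else 1.0
    for i in range(h):
        prod *= ((1 << (h - i)) + c) ** (1 << i)
    return prod


def pi_c_gfb_direct(n: int, c: Real) -> Real:
    """pi_c(gfb(n)) without the subtree-size counts.

    Let k_n = ceil(log2 n) and d_n = n - 2^(k_n - 1), the excess over the
    next lower power of two.  If n = 2^(k_n) the GFB tree is fully
    balanced and pi_c is prod_{i=0}^{k_n - 1} (2^(k_n - i) + c)^(2^i).
    Otherwise gfb(n) is the fully balanced tree of height k_n - 1 with d_n
    leaves replaced by cherries from left to right, and the product is
    corrected factor by factor:

    * (2 + c)^(d_n) for the d_n new cherries;
    * ((2^(i+1) + c)/(2^i + c))^floor(d_n / 2^i) for the completely
      filled subtrees of each size 2^i that grew to size 2^(i+1);
    * (2^i + (d_n mod 2^i) + c)/(2^i + c) for the single partially filled
      subtree at each scale where d_n mod 2^i != 0.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if c <= -2:
        raise ValueError(f"c must exceed -2, got {c}")
    exact = _exact_c(c)
    cc: Real = int(c) if exact else c
    k = ceil_log2(n)
    d = n - (1 << (k - 1))
    if d == 1 << (k - 1):  # n is a power of two
        return _pi_c_fb(k, cc, exact)
    prod = _pi_c_fb(k - 1, cc, exact)
    if exact:
        prod = Fraction(prod)
    prod *= (2 + cc) ** d
    for i in range(1, k):
        full = d >> i  # floor(d / 2^i)
        if full:
            num = (1 << (i + 1)) + cc
            den = (1 << i) + cc
            prod *= (num ** full) / (den ** full) if not exact else \
                Fraction(num, 1) ** full / Fraction(den, 1) ** full
        rem = d % (1 << i)
        if rem:
            num = (1 << i) + rem + cc
            den = (1 << i) + cc
            prod *= Fraction(num, den) if exact else num / den
    if exact:
        assert prod.denominator == 1
        return int(prod)
    return prod


def _log(x: Real, base: Real) -> float:
    if base == 2:
        return math.log2(x)
    if base in ("e", math.e):
        return math.log(x)
    return math.log(x) / math.log(base)


def min_s_hat(n: int, base: Real = 2) -> float:
    """Minimum of the s-hat statistic over all shapes on n leaves:
    log of prod (i - 1)^{a_n(i)}, attained uniquely by gfb(n)."""
    if n <= 2:
        if n < 1:
            raise ValueError(f"n must be a positive integer, got {n}")
        return 0.0
    return _log(pi_c_gfb_via_counts(n, -1), base)


def min_q(n: int, base: Real = 2) -> float:
    """Minimum of the Q-shape statistic over all shapes on n leaves:
    log of prod i^{a_n(i)}, attained uniquely by gfb(n)."""
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    if n == 1:
        return 0.0
    return _log(pi_c_gfb_via_counts(n, 0), base)


def gfb_value_sequence(c: int, n_max: int) -> list[int]:
    """(pi_c(gfb(n)))_{n=1..n_max} as exact integers (c integer, c > -2).

    With c = -1 this is the minimal prod(n_v - 1) sequence
    1, 1, 2, 3, 8, 15, 36, 63, 192, 405, 1080, 2079, 6048, 12285, 31752,
    59535, 193536, ...; c = 0 gives the minimal subtree-size product.
    """
    if c <= -2:
        raise ValueError(f"c must exceed -2, got {c}")
    out = [1]  # n = 1: empty product
    out.extend(pi_c_gfb_via_counts(n, c) for n in range(2, n_max + 1))
    return out[:n_max]
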