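"""Subtree-size based imbalance indices.

Every index here is a function of the multiset of pending-subtree sizes
{n_v : v internal}.  Two families cover all of them:

* the sum family  Phi_f(T) = sum_v f(n_v)  for a per-vertex function f,
* the product family  pi_c(T) = prod_v (n_v + c)  for a constant c > -2.

The Sackin index is Phi_f with f = identity, the s-hat shape statistic is
Phi_f with f(i) = log(i - 1), and the Q-shape statistic uses f(i) = log i.
Logarithms default to base 2 (the usual convention for binary trees); the
natural log is available as well since some reported values use it and
rankings are base-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

from .tree_core import TreeShape

__all__ = [
    "IndexFunction",
    "sackin_index",
    "s_hat_index",
    "q_shape_index",
    "phi_index",
    "pi_index",
    "sackin",
    "s_hat",
    "q_shape",
    "phi",
    "pi_c",
]

Real = Union[int, float]


def _log(x: float, base: Real) -> float:
    if base == 2:
        return math.log2(x)
    if base in ("e", math.e):
        return math.log(x)
    return math.log(x) / math.log(base)


def sackin(t: TreeShape) -> int:
    """Sackin index S(T) = sum of n_v over internal vertices (0 for n = 1)."""
    return sum(v.leaf_count for v in t.internal_vertices())


def s_hat(t: TreeShape, base: Real = 2) -> float:
    """s-hat shape statistic: sum of log(n_v - 1); cherries contribute 0."""
    return sum(_log(v.leaf_count - 1, base)
               for v in t.internal_vertices() if v.leaf_count > 2)


def q_shape(t: TreeShape, base: Real = 2) -> float:
    """Q-shape statistic: sum of log(n_v) over internal vertices."""
    return sum(_log(v.leaf_count, base) for v in t.internal_vertices())


def phi(t: TreeShape, f: Callable[[Real], float]) -> float:
    """Phi_f(T) = sum of f(n_v) over internal vertices (empty sum = 0)."""
    total = 0.0
    for v in t.internal_vertices():
        try:
            total += f(v.leaf_count)
        except Exception as exc:
            raise ValueError(
                f"f failed at internal vertex of size {v.leaf_count}"
            ) from exc
    return total


def _is_integral(c: Real) -> bool:
    return isinstance(c, int) or (isinstance(c, float) and c.is_integer())


def pi_c(t: TreeShape, c: Real) -> Real:
    """Product function pi_c(T) = prod of (n_v + c), c > -2.

    All factors are positive since n_v >= 2.  Integer c is evaluated in
    exact integer arithmetic (empty product = 1 for the single-vertex
    shape), so e.g. the pi_{-1} sequence values are bit-exact.
    """
    if c <= -2:
        raise ValueError(f"c must exceed -2, got {c}")
    if _is_integral(c):
        ci = int(c)
        prod = 1
        for v in t.internal_vertices():
            prod *= v.leaf_count + ci
        return prod
    prod = 1.0
    for v in t.internal_vertices():
        prod *= v.leaf_count + c
    return prod


# ---------------------------------------------------------------------------
# Declared index objects with admissibility flags
# ---------------------------------------------------------------------------

_FLAG_GRID = [2.0, 2.5, 3.0, 4.0, 5.0, 7.0, 10.0, 16.0, 23.0, 32.0, 47.0, 64.0]


@dataclass(frozen=True)
class IndexFunction:
    """A declared imbalance index: a Phi_f member, a pi_c member, or one of
    the named classics.

    The extremal theory (unique minimum at the GFB tree, unique maximum at
    the caterpillar) applies when f is strictly increasing and strictly
    concave; the declared flags are spot-checked numerically on a grid in
    [2, 64] before the index is admitted to extremal-property claims, not
    trusted or proven.
    """

    kind: str  # sackin | s_hat | q_shape | phi | pi
    f: Optional[Callable[[Real], float]] = None
    c: Optional[Real] = None
    base: Real = 2
    strictly_increasing: bool = True
    strictly_concave: bool = True
    name: str = ""

    def __post_init__(self):
        if self.kind not in {"sackin", "s_hat", "q_shape", "phi", "pi"}:
            raise ValueError(f"unknown index kind {self.kind!r}")
        if self.kind == "pi":
            if self.c is None or self.c <= -2:
                raise ValueError("c must exceed -2")
        if self.kind == "phi" and self.f is None:
            raise ValueError("phi index requires f")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        if self.kind == "pi":
            return f"pi_c(c={self.c})"
        return self.kind

    def per_vertex(self) -> Callable[[Real], float]:
        """The per-internal-vertex function f defining this index as Phi_f
        (for pi this is log_base(i + c), whose Phi-sum is log pi_c)."""
        if self.kind == "sackin":
            return lambda i: float(i)
        if self.kind == "s_hat":
            return lambda i: _log(i - 1, self.base) if i > 2 else 0.0
        if self.kind == "q_shape":
            return lambda i: _log(i, self.base)
        if self.kind == "pi":
            return lambda i: _log(i + self.c, self.base)
        return self.f

    def evaluate(self, t: TreeShape) -> Real:
        if self.kind == "sackin":
            return sackin(t)
        if self.kind == "s_hat":
            return s_hat(t, self.base)
        if self.kind == "q_shape":
            return q_shape(t, self.base)
        if self.kind == "pi":
            return pi_c(t, self.c)
        return phi(t, self.f)

    __call__ = evaluate

    def check_flags(self) -> None:
        """Spot-check the declared monotonicity/concavity numerically.

        Raises ``ValueError`` naming the violated flag if a declared
        property fails on the check grid.
        """
        g = self.per_vertex()
        if self.strictly_increasing:
            for x in _FLAG_GRID:
                if not g(x + 1) > g(x):
                    raise ValueError(
                        f"{self.label}: declared strictly_increasing but "
                        f"f({x + 1}) <= f({x})")
        if self.strictly_concave:
            for x in _FLAG_GRID:
                for y in _FLAG_GRID:
                    if x < y:
                        mid = (x + y) / 2
                        if not g(mid) > (g(x) + g(y)) / 2:
                            raise ValueError(
                                f"{self.label}: declared strictly_concave "
                                f"but midpoint inequality fails on "
                                f"[{x}, {y}]")


def sackin_index() -> IndexFunction:
    """Sackin index: strictly increasing, not concave (f is linear)."""
    return IndexFunction(kind="sackin", strictly_concave=False)


def s_hat_index(base: Real = 2) -> IndexFunction:
    return IndexFunction(kind="s_hat", base=base)


def q_shape_index(base: Real = 2) -> IndexFunction:
    return IndexFunction(kind="q_shape", base=base)


def phi_index(f: Callable[[Real], float], *, strictly_increasing: bool = True,
              strictly_concave: bool = True, name: str = "") -> IndexFunction:
    return IndexFunction(kind="phi", f=f,
                         strictly_increasing=strictly_increasing,
                         strictly_concave=strictly_concave, name=name)


def pi_index(c: Real, base: Real = 2) -> IndexFunction:
    return IndexFunction(kind="pi", c=c, base=base)
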