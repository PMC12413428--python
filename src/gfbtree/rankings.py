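"""Exhaustive extremal verification and index-ranking comparison.

Any strictly increasing, strictly concave per-vertex function f yields an
imbalance index Phi_f with the GFB tree as unique minimizer and the
caterpillar as unique maximizer; the product family pi_c (c > -2) induces
the same rankings as Phi_f with f = log(x + c).  These theorems are recast
here as finite checks over the full shape enumeration at fixed n, plus the
two constructive tree pairs showing (a) that distinct c rank some pair of
trees in opposite order, and (b) that some pairs differing in just two
subtree sizes are ranked identically by every c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from scipy.stats import kendalltau

from .generators import caterpillar, enumerate_shapes, gfb
from .indices import IndexFunction, pi_c
from .tree_core import TreeShape, join

__all__ = [
    "RankingTable",
    "ExtremaReport",
    "RankingComparison",
    "rank_shapes",
    "verify_extrema",
    "compare_rankings",
    "pi_disagreement_pair",
    "pi_agreement_pair",
]

Real = Union[int, float]
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class RankingTable:
    """All shapes of one size ranked by one index (rank 1 = most balanced).

    Tied shapes share the minimal rank of their block; rows are sorted by
    (value ascending, canonical key).
    """

    n: int
    index_label: str
    rows: tuple[tuple[TreeShape, Real, int], ...]  # (shape, value, rank)

    @property
    def min_shapes(self) -> set[TreeShape]:
        first_rank = self.rows[0][2]
        return {t for t, _, r in self.rows if r == first_rank}

    @property
    def max_shapes(self) -> set[TreeShape]:
        last_rank = self.rows[-1][2]
        return {t for t, _, r in self.rows if r == last_rank}

    def rank_of(self, t: TreeShape) -> int:
        for shape, _, r in self.rows:
            if shape is t or shape.key == t.key:
                return r
        raise KeyError(t.key)


def _tied(a: Real, b: Real) -> bool:
    if isinstance(a, int) and isinstance(b, int):
        return a == b
    return math.isclose(a, b, rel_tol=_TIE_RTOL, abs_tol=1e-300)


def rank_shapes(n: int, index: IndexFunction) -> RankingTable:
    """Evaluate an admissible index on every shape of size n and rank.

    The index's declared flags are spot-checked first; an inadmissible
    declaration raises ``ValueError`` naming the violated flag.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    index.check_flags()
    shapes = enumerate_shapes(n)
    scored = sorted(((index(t), t) for t in shapes),
                    key=lambda vt: (vt[0], vt[1].key))
    rows = []
    rank = 1
    for i, (value, t) in enumerate(scored):
        if i > 0 and not _tied(value, scored[i - 1][0]):
            rank = i + 1
        rows.append((t, value, rank))
    return RankingTable(n=n, index_label=index.label, rows=tuple(rows))


@dataclass(frozen=True)
class ExtremaReport:
    n: int
    index_label: str
    min_shapes: set
    max_shapes: set
    min_unique: bool
    max_unique: bool
    min_is_gfb: bool
    max_is_caterpillar: bool


def verify_extrema(n: int, index: IndexFunction) -> ExtremaReport:
    """Exhaustively locate the index's minimizers and maximizers at size n.

    For a strictly increasing and strictly concave f the expected outcome
    is a unique minimum at gfb(n) and a unique maximum at caterpillar(n);
    monotonicity alone still forces the caterpillar maximum.
    """
    table = rank_shapes(n, index)
    mins, maxs = table.min_shapes, table.max_shapes
    return ExtremaReport(
        n=n, index_label=index.label,
        min_shapes=mins, max_shapes=maxs,
        min_unique=len(mins) == 1, max_unique=len(maxs) == 1,
        min_is_gfb=gfb(n) in mins,
        max_is_caterpillar=caterpillar(n) in maxs,
    )


@dataclass(frozen=True)
class RankingComparison:
    n: int
    labels: tuple[str, ...]
    tau: list  # pairwise Kendall tau-b matrix (nested lists)
    # per (i, j): one shape pair ranked in opposite order, or None
    disagreements: dict[tuple[int, int], Optional[tuple[TreeShape, TreeShape]]]


def compare_rankings(n: int, indices: Sequence[IndexFunction]
                     ) -> RankingComparison:
    """Pairwise Kendall tau-b between index rankings over all shapes of
    size n, with one witness pair of oppositely ranked shapes per index
    pair where one exists."""
    shapes = enumerate_shapes(n)
    values = [[float(ix(t)) for t in shapes] for ix in indices]
    m = len(indices)
    tau = [[1.0] * m for _ in range(m)]
    disagreements: dict = {}
    for i in range(m):
        for j in range(i + 1, m):
            tau_ij = float(kendalltau(values[i], values[j]).statistic)
            tau[i][j] = tau[j][i] = tau_ij
            witness = None
            for a in range(len(shapes)):
                for b in range(a + 1, len(shapes)):
                    di = values[i][a] - values[i][b]
                    dj = values[j][a] - values[j][b]
                    if di * dj < 0:
                        witness = (shapes[a], shapes[b])
                        break
                if witness:
                    break
            disagreements[(i, j)] = witness
    return RankingComparison(
        n=n, labels=tuple(ix.label for ix in indices), tau=tau,
        disagreements=disagreements)


def _quartet(n11: int, n12: int, n21: int, n22: int
             ) -> tuple[TreeShape, TreeShape, TreeShape, TreeShape]:
    # the four pending subtrees are GFB shapes of the required sizes
    # (any shapes of those sizes would do; GFB fixes a deterministic choice)
    return gfb(n11), gfb(n12), gfb(n21), gfb(n22)


def pi_disagreement_pair(c1: Real, c2: Real
                            ) -> tuple[TreeShape, TreeShape, int, int]:
    """Two trees ranked in opposite order by pi_{c1} and pi_{c2}.

    For -2 < c1 < c2, pick the smallest k with k (c2 - c1) > 2 and the
    smallest integer m with m > k c1 and m + 1 < k c2; the subtree sizes
    n11 = 1, n22 = 2, n21 = 2k + 1, n12 = 4k^2 + 2 + 6k + 2m make the
    critical ratio (2m + 1)/(2k) land strictly inside (c1, c2), so
    T = ((T11,T12),(T21,T22)) and T' = (((T11,T21),T12),T22) satisfy
    pi_{c1}(T) > pi_{c1}(T') and pi_{c2}(T) < pi_{c2}(T').

    Returns (T, T', k, m).
    """
    if not (-2 < c1 < c2):
        raise ValueError(
            f"need -2 < c1 < c2, got c1={c1}, c2={c2}")
    k = 1
    while k * (c2 - c1) <= 2:
        k += 1
    m = math.floor(k * c1) + 1
    while not (m > k * c1 and m + 1 < k * c2):
        m += 1
    n11, n22, n21 = 1, 2, 2 * k + 1
    n12 = 4 * k * k + 2 + 6 * k + 2 * m
    t11, t12, t21, t22 = _quartet(n11, n12, n21, n22)
    T = join(join(t11, t12), join(t21, t22))
    T_prime = join(join(join(t11, t21), t12), t22)
    return T, T_prime, k, m


def pi_disagreement_min_leaves(k: int) -> int:
    """Smallest total leaf count of the disagreement construction at
    parameter k: n11 + n22 + n21 + n12_min = 1 + 2 + (2k+1) + (4k^2+2k+2).

    The n12 bound comes from 2m > -4k (m/k must exceed c1 > -2); at the
    minimal k = 1 (valid when c2 - c1 > 2) the construction already needs
    1 + 2 + 3 + 8 = 14 leaves.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return 1 + 2 + (2 * k + 1) + (4 * k * k + 2 * k + 2)


def pi_agreement_pair(n: int) -> tuple[TreeShape, TreeShape, int]:
    """Two trees differing in exactly two subtree sizes that every pi_c
    ranks the same way.

    Uses the deterministic smallest admissible sizes n11 = 1, n12 = 1,
    n21 = 2, n22 = n - 4 (requires n >= 6 so that n11 < n22 and
    n12 < n21).  With T = ((T11,T12),(T21,T22)) and
    T'' = ((T11,T21),(T12,T22)), the sign of pi_c(T'') - pi_c(T) equals
    sign((n11 n12 + n21 n22) - (n11 n21 + n12 n22)) for every c > -2.

    Returns (T, T'', direction).
    """
    if n < 6:
        raise ValueError(f"n must be >= 6, got {n}")
    n11, n12, n21, n22 = 1, 1, 2, n - 4
    t11, t12, t21, t22 = _quartet(n11, n12, n21, n22)
    T = join(join(t11, t12), join(t21, t22))
    T_dprime = join(join(t11, t21), join(t12, t22))
    direction = (n11 * n12 + n21 * n22) - (n11 * n21 + n12 * n22)
    direction = (direction > 0) - (direction < 0)
    return T, T_dprime, direction
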