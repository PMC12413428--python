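"""Tree-shape probabilities and index expectations under the uniform and
Yule-Harding models.

The uniform model draws one of the (2n-3)!! labeled phylogenetic trees
uniformly; the Yule-Harding model is the forward pure-birth process that
repeatedly replaces a uniformly chosen leaf by a cherry.  Per-labeled-tree
probabilities are lifted to shape probabilities through the labeling count
n!/2^s, and every enumeration-scale probability is carried as an exact
rational.

Expectations of subtree-size indices under any exchangeable distribution
decompose over cluster sizes: E[Phi_f] = sum_k C(n,k) f(k) p_n(k), where
p_n(k) is the probability that a fixed k-subset of leaves is a cluster.
For the Sackin index under the uniform model this yields the closed form
4^(n-1)/C_{n-1} - n (C_m the Catalan numbers); for s-hat the same route
gives an exact cluster-sum formula and printed bounds that are checked
against full enumeration.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Optional, Union

from .generators import enumerate_shapes
from .tree_core import TreeShape, count_labelings, join, leaf

__all__ = [
    "ShapeDistribution",
    "yule_phylo_probability",
    "shape_probability",
    "shape_distribution",
    "sample_yule",
    "cluster_probability_uniform",
    "expected_sackin_uniform",
    "expected_sackin_cluster_sum",
    "expected_s_hat_uniform",
    "s_hat_uniform_printed_sum",
    "s_hat_uniform_bounds",
    "expected_index_by_enumeration",
    "expected_index_monte_carlo",
    "double_factorial",
    "catalan",
]

Real = Union[int, float]
MODELS = ("uniform", "yule")


def double_factorial(m: int) -> int:
    """m!! with the convention (-1)!! = 1; (2n-3)!! counts the labeled
    rooted binary trees on n leaves."""
    if m <= 0:
        return 1
    prod = 1
    while m > 1:
        prod *= m
        m -= 2
    return prod


def catalan(m: int) -> int:
    """The m-th Catalan number C_m = C(2m, m)/(m + 1)."""
    return math.comb(2 * m, m) // (m + 1)


def yule_phylo_probability(t: TreeShape) -> Fraction:
    """Probability of one fixed labeled tree with shape t under the
    Yule-Harding model: (2^(n-1)/n!) * prod 1/(n_v - 1)."""
    n = t.leaf_count
    denom = 1
    for v in t.internal_vertices():
        denom *= v.leaf_count - 1
    return Fraction(2 ** (n - 1), math.factorial(n) * denom)


def shape_probability(t: TreeShape, model: str) -> Fraction:
    """Probability of the shape t (labelings summed out) under the model."""
    n = t.leaf_count
    if model == "uniform":
        return Fraction(count_labelings(t), double_factorial(2 * n - 3))
    if model == "yule":
        return count_labelings(t) * yule_phylo_probability(t)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


@dataclass(frozen=True)
class ShapeDistribution:
    """Exact shape distribution of fixed size n under one model."""

    n: int
    model: str
    probabilities: dict[TreeShape, Fraction]

    def __getitem__(self, t: TreeShape) -> Fraction:
        return self.probabilities[t]


def shape_distribution(n: int, model: str) -> ShapeDistribution:
    """Probabilities of all shapes of size n; sums to 1 exactly."""
    probs = {t: shape_probability(t, model) for t in enumerate_shapes(n)}
    return ShapeDistribution(n=n, model=model, probabilities=probs)


def sample_yule(n: int, seed=None) -> TreeShape:
    """One shape drawn from the Yule-Harding pure-birth process.

    ``seed`` is an int or a ``random.Random``; the process replaces the
    leaf at a uniformly chosen index of the current leaf sequence by a
    cherry until n leaves are present.
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    # nested mutable lists: [] is a leaf, [l, r] an internal node
    root: list = []
    leaves = [root]
    for _ in range(n - 1):
        idx = rng.randrange(len(leaves))
        node = leaves[idx]
        node.append([])
        node.append([])
        leaves[idx] = node[0]
        leaves.append(node[1])

    def freeze(node: list) -> TreeShape:
        if not node:
            return leaf()
        return join(freeze(node[0]), freeze(node[1]))

    return freeze(root)


def cluster_probability_uniform(n: int, k: int) -> Fraction:
    """p_n(k): probability that a fixed k-subset of the n leaves is a
    cluster (the leaf set of a pending subtree) of a uniformly drawn
    labeled tree: C(n-1, k-1) / C(2n-2, 2k-2)."""
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n, got k={k}, n={n}")
    return Fraction(math.comb(n - 1, k - 1), math.comb(2 * n - 2, 2 * k - 2))


def expected_sackin_uniform(n: int) -> Fraction:
    """E[Sackin] under the uniform model: 4^(n-1)/C_{n-1} - n, exactly."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    return Fraction(4 ** (n - 1), catalan(n - 1)) - n


def expected_sackin_cluster_sum(n: int) -> Fraction:
    """E[Sackin] via the exchangeable cluster decomposition
    sum_{k=1}^{n-1} C(n,k) k p_n(k); identical to the closed form (the
    k = 1 term exactly offsets the omitted k = n root term)."""
    return sum((math.comb(n, k) * k * cluster_probability_uniform(n, k)
                for k in range(1, n)), Fraction(0))


def _log(x: Real, base: Real) -> float:
    if base == 2:
        return math.log2(x)
    if base in ("e", math.e):
        return math.log(x)
    return math.log(x) / math.log(base)


def s_hat_uniform_printed_sum(n: int, base: Real = 2) -> float:
    """The cluster sum for E[s-hat] truncated at k = n - 1, i.e. without
    the root cluster's fixed contribution log(n - 1).

    Exposed for comparison only: unlike the Sackin cluster sum, nothing
    offsets the missing k = n term here (the k = 2 term is already 0), so
    this undershoots the true expectation by exactly log(n - 1).  Kept
    separate so the discrepancy can be measured, never asserted as the
    expectation.
    """
    return float(sum(
        math.comb(n, k) * _log(k - 1, base) * cluster_probability_uniform(n, k)
        for k in range(3, n)))


def expected_s_hat_uniform(n: int, base: Real = 2) -> float:
    """E[s-hat] under the uniform model via cluster sizes:
    log(n - 1) + sum_{k=2}^{n-1} C(n,k) log(k-1) p_n(k).

    The root of every tree is a cluster of size n contributing the fixed
    term log(n - 1); the remaining clusters are covered by the sum.
    Matches exhaustive enumeration (a tested equivalence at n <= 10).
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    return _log(max(n - 1, 1), base) + s_hat_uniform_printed_sum(n, base)


@dataclass(frozen=True)
class SHatBoundsReport:
    """Printed bounds for E_U[s-hat] with an enumeration check.

    ``lower`` is (log n / n) (4^(n-1)/C_{n-1} - n) and ``upper`` the
    Sackin expectation itself, exactly as printed.  The upper bound is
    sound (s-hat <= Sackin pointwise); the lower bound fails at small n
    (its proof's bound log(k-1)/k >= log(n-1)/n is false at k = 2), so it
    is reported, not asserted.  ``exact`` and the containment flags are
    filled by enumeration when n <= 12.
    """

    n: int
    base: Real
    lower: float
    upper: float
    exact: Optional[float]
    exact_above_lower: Optional[bool]
    exact_below_upper: Optional[bool]


def s_hat_uniform_bounds(n: int, base: Real = 2,
                         enumeration_limit: int = 12) -> SHatBoundsReport:
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    sackin_exp = float(expected_sackin_uniform(n))
    lower = _log(n, base) / n * sackin_exp
    upper = sackin_exp
    exact = above = below = None
    if n <= enumeration_limit:
        from .indices import s_hat
        exact = expected_index_by_enumeration(
            n, lambda t: s_hat(t, base), "uniform")
        above = exact >= lower
        below = exact <= upper
    return SHatBoundsReport(n=n, base=base, lower=lower, upper=upper,
                            exact=exact, exact_above_lower=above,
                            exact_below_upper=below)


def expected_index_by_enumeration(n: int, index: Callable[[TreeShape], Real],
                                  model: str) -> float:
    """Exact expectation of an index by summing over all shapes of size n.

    Probabilities are exact rationals; the index values are combined in
    floating point.  Practical for n <= ~12.
    """
    if n > 16:
        raise ValueError(
            f"exhaustive enumeration at n={n} is impractical; use "
            "expected_index_monte_carlo")
    dist = shape_distribution(n, model)
    return float(sum(float(p) * float(index(t))
                     for t, p in dist.probabilities.items()))


def expected_index_monte_carlo(n: int, index: Callable[[TreeShape], Real],
                               reps: int, seed) -> tuple[float, float]:
    """Monte-Carlo (mean, stderr) of an index under the Yule-Harding model.

    ``seed`` is required for reproducibility.  stderr is the sample
    standard deviation over sqrt(reps) (0 when reps == 1).
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    total = 0.0
    total_sq = 0.0
    for _ in range(reps):
        x = float(index(sample_yule(n, rng)))
        total += x
        total_sq += x * x
    mean = total / reps
    if reps == 1:
        return mean, 0.0
    var = max(total_sq / reps - mean * mean, 0.0) * reps / (reps - 1)
    return mean, math.sqrt(var / reps)
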