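# Methods

## Objects and conventions

The package works with *tree shapes*: isomorphism classes of rooted trees
whose vertices have out-degree 0 or 2, leaves unlabeled. A shape is stored
canonically — at every internal vertex the two children are ordered by
(leaf count, canonical key), ascending, where the canonical key is the
anonymous-leaf Newick string of the subtree. Shapes are interned, so
isomorphism is identity comparison and memoized enumeration is cheap. The
single-vertex tree (n = 1, the root is its only leaf) is a first-class
value: every index sum over internal vertices is an empty sum (0) and
every product an empty product (1) for it.

All structural arithmetic is integer-exact: ⌈log₂ n⌉ is computed as the
bit length of n − 1, never by floating-point log. Newick input (parsed via
dendropy) tolerates labels, branch lengths, comments and arbitrary child
order, all of which are discarded; output is the canonical anonymous-leaf
dialect, and parse(write(t)) is the identity (tested over the full
enumeration through n = 12).

**Logarithm base.** Indices default to base 2, the usual convention for
binary trees. Base e is equally supported because the reference values for
the three 10-leaf example shapes (12.8, 6.0, 6.4) are natural-log
evaluations of the underlying products (ln 9! ≈ 12.80, ln 405 ≈ 6.00,
ln 576 ≈ 6.36); rankings and extremal sets are base-invariant, so nothing
downstream depends on the choice. Neither convention is silently "fixed":
both are exposed and the ambiguity is documented here.

## Constructions

- *Caterpillar*: repeatedly attach a leaf; one cherry, height n − 1.
- *Fully balanced* T^fb_h: recursive self-join, 2^h leaves at depth h.
- *Maximally balanced*: recursive (⌈n/2⌉, ⌊n/2⌋) splits; every internal
  vertex balanced.
- *GFB*: greedy forest clustering — start from n single vertices, join two
  minimal-size trees until one remains. Ties among minimal-size trees are
  broken by canonical order by default; a seeded RNG tie-break is available
  and the result is tie-break independent (property-tested through n = 12
  over several random orders, consistent with the closed-form root-split
  sizes that leave no freedom in the size sequence). The intermediate
  forests are exposed (`gfb_forests`) so the structural invariant that at
  most one forest member has non-power-of-two size can be checked directly.
- *Complete*: fully balanced tree of height ⌊log₂ n⌋ with the excess
  n − 2^⌊log₂ n⌋ leaves replaced by cherries left to right, on the
  construction's own left-to-right leaf order (any fixed order gives an
  isomorphic result; the equality complete(n) = gfb(n) is tested for
  n ≤ 64 rather than assumed).

Enumeration of all shapes of size n recurses over unordered root splits
(a ≤ b, a + b = n), with the a = b case iterating over unordered shape
pairs including equal pairs; counts follow the Wedderburn–Etherington
numbers (1, 1, 1, 2, 3, 6, 11, 23, 46, 98, …). Practical to n ≈ 20.

## Index families

Φ_f sums a per-vertex function f(n_v); π_c multiplies (n_v + c), with
c > −2 so every factor is positive (the smallest pending subtree has
size 2). π_c with integer c is evaluated in exact integer arithmetic so
sequence values are bit-exact; log₂ π_c equals Φ_f with f = log₂(x + c),
which is how the product family inherits the sum family's extremal theory.

Users supplying their own f declare monotonicity/concavity flags; the
library spot-checks the declarations numerically on a grid in [2, 64]
(successor increase, midpoint inequality) before admitting the index to
extremal claims. This is a guard against mis-declared functions, not a
proof; the grid is fixed and documented rather than adaptive.

## Closed forms

The subtree-size spectrum a_n(i) of the GFB tree uses the four-case
formula keyed on whether i is a power of two and on n mod i (respectively
(n − i) mod 2^(k_i − 1) with k_i = ⌈log₂ i⌉). From it, π_c(gfb(n)) =
Π (i + c)^{a_n(i)}, and the minimum ŝ and Q values are the logarithms of
that product at c = −1 and c = 0.

A second, independent route computes π_c(gfb(n)) directly from the
complete-tree decomposition: start from the fully balanced tree one level
down, multiply in (2 + c) per new cherry, upgrade completely filled
subtrees of size 2^i to 2^(i+1), and apply one partial-fill correction per
scale where d_n mod 2^i ≠ 0 (d_n the excess over the next lower power of
two). The source display of this formula is garbled, so the implementation
follows the constructive derivation and is pinned by *exact rational
equality* with the spectrum route for n = 2..256 at integer c and to
1e−9 relative at non-integer c — the spectrum route is treated as ground
truth.

## Models

The uniform model puts equal mass on all (2n − 3)!! labeled trees; the
Yule–Harding model is the pure-birth process replacing a uniformly chosen
leaf by a cherry. Per-labeled-tree probabilities are lifted to shape
probabilities via the labeling count n!/2^s (s = number of internal
vertices with isomorphic child subtrees). All enumeration-scale
probabilities are exact `Fraction`s; expectations involving logarithms are
floats checked to 1e−12 at n ≤ 10.

Expectations of subtree-size indices under any exchangeable distribution
decompose over cluster sizes with p_n(k) = C(n−1, k−1)/C(2n−2, 2k−2) under
the uniform model (brute-force verified against all labeled trees for
n ≤ 7). Two printed claims from the surrounding literature fail
numerically and are deliberately *reported, never asserted*:

- the cluster-sum formula for E[ŝ] truncated at k = n − 1 omits the root
  cluster's fixed contribution log(n − 1). Unlike the analogous Sackin sum
  — where the k = 1 term exactly offsets the omitted k = n term, an
  identity the suite tests — nothing compensates here (the k = 2 term is
  already zero). The corrected form (root term added) matches exhaustive
  enumeration to 1e−12 for n = 2..10; the truncated sum is exposed
  separately (`s_hat_uniform_printed_sum`) and undershoots by exactly
  log(n − 1) (at n = 4, base 2: 0.8 vs 2.38496).
- the stated lower bound (log n / n)·E[Sackin] for E_U[ŝ] fails at small n
  (n = 4: bound 4.4 vs exact 2.38496; the inequality log(k−1)/k ≥
  log(n−1)/n used to derive it is false at k = 2). The bounds report
  carries the lower bound alongside the enumerated exact value with
  containment flags; only the upper bound (E[ŝ] ≤ E[Sackin], sound because
  ŝ ≤ Sackin pointwise) is asserted.

The Yule sampler takes an explicit seed (int or `random.Random`), picks
the replaced leaf by index into the current leaf sequence, and is
validated against exact shape probabilities; Monte-Carlo expectations
report mean and standard error and are checked to within four standard
errors of enumeration values.

## Constructive ranking pairs

Two constructions show the richness of the π_c family. For any
−2 < c₁ < c₂, choosing the smallest k with k(c₂ − c₁) > 2 and the smallest
integer m with m > kc₁ and m + 1 < kc₂ yields subtree sizes (1, 2, 2k+1,
4k² + 2 + 6k + 2m) whose critical ratio (2m+1)/(2k) lies strictly inside
(c₁, c₂), producing two trees ranked in opposite order by π_{c₁} and
π_{c₂}; at the minimal parameter k = 1 the construction needs
1 + 2 + 3 + 8 = 14 leaves. Conversely, for every n ≥ 6 the sizes
(1, 1, 2, n − 4) give two trees differing in exactly two subtree sizes
that *every* π_c ranks the same way, the direction determined by the
c-free sign of (n₁₁n₁₂ + n₂₁n₂₂) − (n₁₁n₂₁ + n₁₂n₂₂). The four pending
subtrees are taken as GFB shapes of the required sizes (the proofs leave
them arbitrary; GFB fixes a deterministic choice). Tree topologies follow
the π-ratio identities: T = ((T₁₁,T₁₂),(T₂₁,T₂₂)),
T′ = (((T₁₁,T₂₁),T₁₂),T₂₂), T″ = ((T₁₁,T₂₁),(T₁₂,T₂₂)).

Ranking comparison uses Kendall τ-b (tie-aware, scipy) — a deliberate
implementation choice, since no particular correlation measure is
canonical here — plus, per index pair, one witness pair of shapes ranked
in opposite order when one exists. Ranking tables use competition ranks
(tied block shares its minimal rank); ties between floating-point index
values are detected at 1e−12 relative tolerance, which is far below the
smallest genuine gap between distinct integer-product logarithms at the
enumeration sizes used.

## Problem sizes and verification scope

Exhaustive verification runs over the complete shape enumeration for
n = 2..12 (451 shapes at n = 12) for extremal uniqueness, n ≤ 10 for model
identities, n ≤ 64 for the construction equivalences and forest
instrumentation, and n ≤ 256 for the closed-form equivalences — sizes at
which every claim is checked against an independent route (direct
counting, brute-force labeled-tree enumeration, or exact rational
recomputation) in seconds. These finite checks replace the general proofs:
they verify the implementation, and they confirm the theorems precisely on
the ranges checked, not beyond.

## Known limitations

- Exhaustive enumeration is exponential; shape-level operations beyond
  n ≈ 20 must go through the closed forms or sampling.
- No closed form is provided for Yule–Harding expectations of ŝ (none is
  known); the Monte-Carlo estimator covers that regime.
- Colless, total cophenetic and the other surveyed indices are out of
  scope, as are labeled-tree objects with taxon maps, branch lengths and
  non-binary trees.
- π_c for non-integer c uses floating point; for trees with many hundreds
  of leaves the raw product can overflow, and the log-scale form
  (Φ with f = log(x + c)) should be used instead — rankings are identical.
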