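# gfbtree

Tree balance machinery for rooted binary trees, centered on the
**greedy-from-the-bottom (GFB) tree** and the two families of subtree-size
based imbalance indices it minimizes.

## The problem

Phylogenetics (and computer science more broadly) measures how balanced a
rooted binary tree is with *imbalance indices*: shape statistics that are
maximal on the caterpillar tree and minimal on the fully balanced tree when
the leaf count n is a power of two. Classic examples built from
pending-subtree sizes n_v (the leaf count below each internal vertex v):

- **Sackin index** S(T) = Σ_v n_v
- **ŝ-shape statistic** ŝ(T) = Σ_v log(n_v − 1)
- **Q-shape statistic** Q(T) = Σ_v log n_v

These sit inside two general families,

    Φ_f(T) = Σ_v f(n_v)          (f strictly increasing, strictly concave)
    π_c(T) = Π_v (n_v + c)       (constant c > −2)

and for every admissible member the **GFB tree** — obtained by repeatedly
joining the two smallest trees in a forest of n single leaves — is the
*unique* minimizer for every n, while the caterpillar is the unique
maximizer. The GFB tree coincides with the "complete tree" (fully balanced
tree of the next lower power of two with cherries attached left to right),
its subtree-size spectrum a_n(i) has a four-case closed form, and from that
follow exact formulas for π_c(T^gfb_n) and for the minimum values of ŝ and
Q. The package implements all of this plus shape probabilities and index
expectations under the uniform and Yule–Harding models, with the theorems
recast as exhaustively verifiable property suites over the full shape
enumeration.

## Worked example

```python
>>> from gfbtree import gfb, caterpillar, s_hat, pi_c, subtree_sizes
>>> sorted(subtree_sizes(gfb(10)).elements())
[2, 2, 2, 2, 2, 4, 4, 6, 10]
>>> round(s_hat(caterpillar(10), "e"), 1)   # ln 9!  — most imbalanced
12.8
>>> round(s_hat(gfb(10), "e"), 1)           # ln 405 — unique minimum
6.0
>>> pi_c(gfb(10), -1)                       # exact integer product
405
```

The value 405 = 9·5·3² is the product of (n_v − 1) over the nine internal
vertices of the 10-leaf GFB tree; its logarithm is the smallest ŝ value any
10-leaf shape can attain, and `gfb_value_sequence(-1, 17)` reproduces the
whole exact sequence 1, 1, 2, 3, 8, 15, 36, 63, 192, 405, …, 193536.

The same things are available from the shell:

```sh
$ gfbtree generate --kind gfb --n 10
(((,),(,)),((,),((,),(,))));
$ gfbtree sequence --c -1 --nmax 10
1
1
2
3
8
15
36
63
192
405
$ gfbtree verify --n 10 --stat shat
{"n": 10, "index": "s_hat", ..., "min_unique": true, "min_is_gfb": true,
 "max_unique": true, "max_is_caterpillar": true}
```

Subcommands: `generate`, `enumerate`, `index`, `minval`, `sequence`,
`expect`, `rank`, `verify`, `construct` (see `gfbtree --help`).

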