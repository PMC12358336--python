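# Methods

## The model

A group-based substitution model identifies the character states with a
finite abelian group `G` (Klein four-group for JC/K2P/K3P nucleotide
models; odd orders arise from codon models and amino-acid recodings).
On a tree, the Fourier transform makes the joint leaf distribution a
monomial map of the edge parameters. The 3-sunlet — the minimal
semi-directed level-1 network with a 3-cycle: leaf edges `e1, e2, e3`,
cycle edge `e4`, reticulation edges `e5, e6` — displays two trees `T1`
(delete `e6`) and `T2` (delete `e5`), and its transformed coordinate for
a consistent leaf-labelling `g = (g1, g2, g3)`, `g1 + g2 + g3 = 0`, is
the sum of the two tree monomials

    phi(w)_g = w1^g1 w2^g2 w3^g3 w4^(g1+g2) w5^g1
             + w1^g1 w2^g2 w3^g3 w4^g2      w6^g1.

Throughout `ell + 1 = |G|` (trivial automorphism subgroup; the types
carry group elements directly, and a non-trivial orbit layer is out of
scope — every computation here is for the general group-based model).
The variety `V` is the closure of the image of `phi`; parameter counting
bounds its affine dimension by `5*ell + 1`, the *expected dimension*.

## Dimension lower bounds from tropical Jacobians

For a weight vector `lambda` on the `6(ell+1)` parameters, each
coordinate of the tropicalized map takes the minimum of the two
monomials' weights. Where no tie occurs the tropical map is linear with
a 0/1 matrix `A_lambda` whose column for `g` is the exponent vector of
the lighter monomial, and `dim V >= rank_Q A_lambda`. All shared factors
cancel in the comparison, which collapses to the reduced coordinates
`mu_g = lambda6^g - lambda5^g` and `nu = lambda4`:

    g = (g1, g2, .) -> T1   iff   nu_{g1+g2} - nu_{g2} < mu_{g1}

(for `g1 = 0` this reads `0 < mu_0`). Ties raise an error rather than
being broken silently: on a tie `A_lambda` is undefined and any value
returned there would certify nothing.

Ranks are computed exactly: fraction-free Bareiss elimination over
Python integers is the certified path, and a Monte-Carlo reduction
modulo the prime 2147483659 (> 2^31; products stay inside int64) serves
as a bulk screening path inside the sampler. Reduction mod p can only
lower the rank, and every reported maximum is re-verified with the exact
routine before it is returned.

## The tie arrangement and its chambers

The tie loci form a hyperplane arrangement in `(mu, nu)`-space:
`mu_0 = 0` (flipping it reassigns all `|G|` columns with `g1 = 0`) plus
one hyperplane `mu_{g1} = nu_{g1+g2} - nu_{g2}` per pair `(g1 != 0, g2)`
— `1 + ell(ell+1)` in total. A chamber (maximal open region) carries one
constant `A_lambda`, hence one rank; chambers correspond to the monomial
initial ideals of the parameterization ideal, i.e. its toric
degenerations.

Chambers are enumerated exhaustively as feasible sign vectors. The
feasibility test eliminates each `mu_{g1}`: for fixed signs, `mu_{g1}`
needs the open interval between the largest "T1-side" difference
`d = nu_{g1+g2} - nu_{g2}` and the smallest "T2-side" difference, which
is nonempty iff the pairwise strict system `d_p < d_n` over `nu` alone
is solvable. That system is decided by an exact max-slack simplex over
rationals (`_lp.py`): maximize `s` subject to `L_k(nu) + s <= 0` in a
box; the optimum is positive iff the open region is nonempty, and the
solution is an interior witness. Because every constraint row has zero
coefficient sum, the shifted problem has nonnegative right-hand sides
and a single-phase simplex with Bland's rule suffices. The box bound
only makes the LP bounded — the cone is homogeneous, so it cannot change
feasibility. Each witness's sign vector is re-verified against the
requested one. The enumeration walks sign patterns block-by-`g1`,
pruning any prefix whose partial system is already infeasible; a budget
guard refuses arrangements beyond 13 hyperplanes (i.e. beyond order 4)
unless forced, since the sign-vector space grows as `2^{ell(ell+1)+1}`.

Adjacency between chambers differing in one sign is confirmed by a
facet-interior test: equality on the flipped hyperplane, strictness
elsewhere — the same `nu`-difference LP with the pivot difference wedged
strictly between the two sides of its block. `mu_0`-flips always share a
facet because `mu_0` appears in no other constraint. *Locally maximal
deficient* chambers (non-maximal rank, no neighbour of larger rank) are
reported with the "less than or equal" neighbour criterion; the strict
variant is available behind a flag but is always empty, because every
chamber has an equal-rank `mu_0`-flip neighbour.

## The deterministic weight construction (odd order)

For odd `|G| = 2t + 1 >= 7`, fix the inverse-free subset `X` (first-seen
member of each `±` pair in enumeration order; any valid `X` is
accepted). The recipe needs `nu_0` "large" and the other `nu` values
"small" and distinct, and each `mu_g` (`g` in `X`) strictly between
`max_{h != -g}(nu_{g+h} - nu_h)` and `nu_0 - nu_{-g}`, mirrored as
`mu_{-g} = -mu_g`, with `mu_0 < 0`. The concrete numbers used are
`nu_0 = 3`, `nu = j/(ell+1)` on the j-th nonzero element, interval
midpoints for `mu`, and `mu_0 = -1`: then every nonzero-`nu` difference
lies in `(-1, 1)` while `nu_0 - nu_{-g} >= 2`, so all the required
inequalities hold strictly with margin and the construction can never
tie. The code verifies the resulting assignment against the target
pattern and the `(t+1)(2t+1) / t(2t+1)` split rather than trusting the
derivation.

Deleting the dependent leaf-1 rows (`r1 = r5 + r6` for every
assignment), sorting T2 columns left, and applying `r4 <- r4 - r2`
yields a block upper-triangular matrix: the T2 block is the 3-star
exponent matrix (rank `3*ell + 1`), the T1 block has rank at least
`2*ell`, so `rank A_lambda = 5*ell + 1` exactly — the expected
dimension. `|G| = 5` is below the block argument's reach and is
certified by seeded sampling instead (rank-21 chambers are plentiful);
`|G| = 3` cannot reach `5*ell + 1 = 11` at all since the ambient space
is 9-dimensional.

For even order the same recipe runs with all order-2 elements included
in `X` and the mirror rule skipped for them (it would force
`mu_g = 0`, a tie). This reproduces the sampled maximum for `Z6` (26)
but provably not for powers of `Z2` (Klein four: 13 versus 15); the
even-order dimension question is certified by sampling, not by this
construction.

## Sampling

Reduced weights are drawn uniformly from `(-1/2, 1/2)^{2(ell+1)}` as
exact dyadic rationals (53-bit numerators over 2^53), so tie detection
is exact integer arithmetic and no LP is needed per sample. Draws are
deduplicated by assignment signature (one bit per labelling — the
signature determines the chamber), and each new region is ranked once.
The lower-bound search is seeded with the four all-one-tree chambers, so
it never reports below `3*ell + 1`, and it is reproducible for fixed
(group, budget, seed). Greedy hill-climbing is deliberately not used:
locally maximal deficient chambers exist (128 for `Z4`) and would trap
it.

## Problem sizes and defaults

* Sampling budgets default to 2*10^4 draws; the even-order maxima
  (`Z6` -> 26, `Z8` -> 36) and the `Z5` certificate (21) are each found
  well inside that budget in seconds.
* Exhaustive censuses are run for `Z3` (92 chambers), `Z4` and
  `Z2 x Z2` (2,328 chambers each) — these take seconds to tens of
  seconds. The `Z5` arrangement (2^21 sign vectors, 113,352 chambers)
  is available behind the budget guard via `scripts/z5_census.py` and
  takes hours; the test suite covers `Z5` by a scaled-down sampled
  census instead. `Z6` and beyond are sampled only.
* The sampled-census cross-check on `Z3` uses 10^5 draws, enough to hit
  all 92 regions with a wide margin at any tested seed.

## Known limitations

* Non-trivial automorphism subgroups (JC/K2P symmetry constraints) are
  not modelled; all results are for the general group-based model.
* The even-order "modified" construction is heuristic; its documented
  shortfall for `(Z2)^k` is reproduced, not repaired.
* Chamber enumeration is exact but exponential; it is a verification
  tool for small groups, not a general-purpose arrangement library.
* The ideal export writes generators of the parameterization's image;
  computing the kernel (phylogenetic invariants) is out of scope — the
  eliminations are computationally infeasible already for `Z5`.
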