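"""Randomized region discovery and dimension lower bounds.

Uniform samples of reduced weights ``(mu, nu)`` in the open cube
``(-1/2, 1/2)^{2|G|}`` are drawn as exact dyadic rationals (53 random
bits of numerator over 2^53), so tie detection is exact integer
arithmetic and every retained weight is a genuine chamber interior
point.  Samples are deduplicated by their tree-assignment signature —
two weights in the same chamber produce the same Jacobian — and each
newly seen region is ranked once.

Bulk ranks use the fast mod-p path (a lower bound that agrees with the
rational rank for all but finitely many primes); the reported maximum is
always re-verified with exact fraction-free elimination before a report
is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from ._linalg import rank_exact, rank_mod_p
from .groups import GroupSpec
from .jacobian import ReducedWeight, TreeAssignment, build_matrix
from .sunlet import exponent_matrices

_DENOM_BITS = 53
_DENOM = 1 << _DENOM_BITS
_HALF = 1 << (_DENOM_BITS - 1)


@dataclass(frozen=True)
class SampleReport:
    """Outcome of a sampling run: regions seen (keyed by assignment
    signature) with their ranks, and the best weight found."""

    group: GroupSpec
    n_samples: int
    seed: int
    max_rank: int
    best_weight: ReducedWeight
    regions_seen: dict[bytes, int]
    ties_discarded: int


def _reduced_from_ints(G: GroupSpec, mu_num: np.ndarray, nu_num: np.ndarray) -> ReducedWeight:
    els = G.elements()
    return ReducedWeight(
        mu={g: Fraction(int(mu_num[i]), _DENOM) for i, g in enumerate(els)},
        nu={g: Fraction(int(nu_num[i]), _DENOM) for i, g in enumerate(els)},
    )


def _assignment_diffs(G: GroupSpec, mu_num: np.ndarray, nu_num: np.ndarray) -> np.ndarray:
    """Signed comparison values per (sample, column): negative means T1.

    Column (g1, g2) compares ``nu_{g1+g2} - nu_{g2}`` with ``mu_{g1}``;
    all quantities share the denominator 2^53, so only the integer
    numerators matter.
    """
    n = G.order
    add = np.asarray(G.add_table, dtype=np.intp)
    i1 = np.repeat(np.arange(n), n)
    i2 = np.tile(np.arange(n), n)
    i12 = add[i1, i2]
    return nu_num[:, i12] - nu_num[:, i2] - mu_num[:, i1]


def sample_regions(G: GroupSpec, n: int, seed: int) -> SampleReport:
    """Draw ``n`` uniform dyadic reduced weights, discard exact ties,
    deduplicate by region, and record one exact rank per region."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    m = G.order
    M1, M2 = exponent_matrices(G)
    regions: dict[bytes, int] = {}
    ties = 0
    best_rank = -1
    best_mu = best_nu = None
    chunk = 4096
    done = 0
    while done < n:
        take = min(chunk, n - done)
        done += take
        mu_num = rng.integers(-(_HALF - 1), _HALF, size=(take, m), dtype=np.int64)
        nu_num = rng.integers(-(_HALF - 1), _HALF, size=(take, m), dtype=np.int64)
        diffs = _assignment_diffs(G, mu_num, nu_num)
        tie_mask = (diffs == 0).any(axis=1)
        ties += int(tie_mask.sum())
        t1 = diffs < 0
        sigs = np.packbits(t1.astype(np.uint8), axis=1)
        for row in range(take):
            if tie_mask[row]:
                continue
            key = sigs[row].tobytes()
            if key in regions:
                continue
            A = np.where(t1[row][None, :], M1, M2)
            rank = rank_mod_p(A)
            regions[key] = rank
            if rank > best_rank:
                best_rank = rank
                best_mu, best_nu = mu_num[row].copy(), nu_num[row].copy()
    if best_mu is None:
        raise RuntimeError("all samples tied (measure-zero event)")
    best = _reduced_from_ints(G, best_mu, best_nu)
    # re-verify the reported maximum with exact arithmetic
    from .jacobian import assign

    exact = rank_exact(build_matrix(G, assign(G, best)).matrix)
    assert exact == best_rank, "fast-path rank disagreed with exact rank at the max"
    return SampleReport(
        group=G,
        n_samples=n,
        seed=seed,
        max_rank=best_rank,
        best_weight=best,
        regions_seen=regions,
        ties_discarded=ties,
    )


def _baseline_weights(G: GroupSpec) -> list[ReducedWeight]:
    """Interior points of the four minimal-rank chambers: all columns to
    one tree, with or without the mu0 flip."""
    els = G.elements()
    zero = {g: Fraction(0) for g in els}
    out = []
    for base in (1, -1):
        for flip0 in (False, True):
            mu = {g: Fraction(base) for g in els}
            if flip0:
                mu[els[0]] = Fraction(-base)
            out.append(ReducedWeight(mu=mu, nu=dict(zero)))
    return out


def certify_lower_bound(
    G: GroupSpec,
    budget: int,
    seed: int,
    target: int | None = None,
) -> tuple[int, ReducedWeight]:
    """Best exact Jacobian rank found within a sampling budget.

    The search is seeded with the four all-one-tree baseline chambers
    (rank ``3*ell + 1``), so the returned bound is never below that; it
    stops early once ``target`` is reached.  Deterministic for fixed
    ``(group, budget, seed)``.
    """
    from .jacobian import assign

    best_rank = -1
    best_rw: ReducedWeight | None = None
    for rw in _baseline_weights(G):
        rank = rank_exact(build_matrix(G, assign(G, rw)).matrix)
        if rank > best_rank:
            best_rank, best_rw = rank, rw
    if target is not None and best_rank >= target:
        return best_rank, best_rw

    rng = np.random.default_rng(seed)
    m = G.order
    M1, M2 = exponent_matrices(G)
    drawn = 0
    chunk = 2048
    while drawn < budget:
        take = min(chunk, budget - drawn)
        drawn += take
        mu_num = rng.integers(-(_HALF - 1), _HALF, size=(take, m), dtype=np.int64)
        nu_num = rng.integers(-(_HALF - 1), _HALF, size=(take, m), dtype=np.int64)
        diffs = _assignment_diffs(G, mu_num, nu_num)
        tie_mask = (diffs == 0).any(axis=1)
        t1 = diffs < 0
        for row in range(take):
            if tie_mask[row]:
                continue
            A = np.where(t1[row][None, :], M1, M2)
            rank = rank_mod_p(A)
            if rank > best_rank:
                rw = _reduced_from_ints(G, mu_num[row], nu_num[row])
                exact = rank_exact(build_matrix(G, assign(G, rw)).matrix)
                if exact > best_rank:
                    best_rank, best_rw = exact, rw
                if target is not None and best_rank >= target:
                    return best_rank, best_rw
    return best_rank, best_rw
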