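"""Exact integer matrix rank.

Tropical Jacobians are small 0/1 integer matrices whose rank over the
rationals is the certified quantity, so ranks are computed exactly with
fraction-free (Bareiss) Gaussian elimination on Python integers — no
floating point anywhere.  A fast Monte-Carlo path reduces modulo a prime
larger than 2^31; reduction mod p can only lower the rank, so callers use
it for bulk screening and re-verify any reported maximum exactly.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

# smallest prime above 2^31; (p-1)^2 < 2^63 so int64 products never overflow
FAST_RANK_PRIME = 2_147_483_659


def rank_exact(M: Iterable[Sequence[int]]) -> int:
    """Rank over Q of an integer matrix, by Bareiss elimination.

    Accepts any nested iterable of integers (including numpy arrays).
    Intermediate entries are minors of the input, so arithmetic is exact
    with Python's arbitrary-precision integers.
    """
    rows = [[int(x) for x in r] for r in M]
    if not rows or not rows[0]:
        return 0
    m, n = len(rows), len(rows[0])
    rank = 0
    prev = 1
    for col in range(n):
        piv = next((r for r in range(rank, m) if rows[r][col] != 0), None)
        if piv is None:
            continue
        rows[rank], rows[piv] = rows[piv], rows[rank]
        pivot_row = rows[rank]
        pv = pivot_row[col]
        for r in range(rank + 1, m):
            row = rows[r]
            factor = row[col]
            for j in range(col, n):
                row[j] = (row[j] * pv - factor * pivot_row[j]) // prev
        prev = pv
        rank += 1
        if rank == m:
            break
    return rank


def rank_mod_p(M: np.ndarray, p: int = FAST_RANK_PRIME) -> int:
    """Rank of an integer matrix over GF(p), vectorized with numpy.

    Always a lower bound for the rank over Q; equal for all but finitely
    many primes.
    """
    A = np.asarray(M, dtype=np.int64) % p
    m, n = A.shape
    rank = 0
    for col in range(n):
        if rank == m:
            break
        nz = np.nonzero(A[rank:, col])[0]
        if nz.size == 0:
            continue
        piv = rank + int(nz[0])
        if piv != rank:
            A[[rank, piv]] = A[[piv, rank]]
        inv = pow(int(A[rank, col]), p - 2, p)
        A[rank] = (A[rank] * inv) % p
        below = A[rank + 1 :, col].copy()
        if below.any():
            A[rank + 1 :] = (A[rank + 1 :] - below[:, None] * A[rank][None, :]) % p
        rank += 1
    return rank
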