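"""Exact rational feasibility of systems of strict linear inequalities.

The chamber machinery needs interior certificates: given integer rows
``L_k``, decide whether some ``x`` in the box ``[-B, B]^d`` satisfies
``L_k(x) < 0`` strictly for every ``k``, and produce such an ``x``.  This
is the max-slack linear program

    maximize s   subject to   L_k(x) + s <= 0,  x in [-B, B]^d,  s <= 1,

whose optimum is positive iff the open region is nonempty.  All systems
fed in here are homogeneous with zero coefficient sum per row (they are
differences of differences of ``nu``-coordinates), so after the shift
``y = x + B`` the right-hand sides are all nonnegative and the slack
basis is feasible: a single-phase dense simplex with Bland's rule
suffices, run on ``fractions.Fraction`` so every certificate is exact.

By default the solver stops as soon as the current vertex has ``s > 0``
(callers need an interior point, not the Chebyshev-style optimum).
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence


def max_slack(
    rows: Sequence[Sequence[int]],
    nvars: int,
    box: int = 1,
    early_exit: bool = True,
) -> tuple[Fraction, list[Fraction]]:
    """Return ``(s, x)`` with ``s`` the (possibly early-exited) slack and
    ``x`` a point achieving it; ``s > 0`` iff the strict system
    ``L_k(x) < 0`` has a solution.

    ``rows`` must have zero coefficient sum (asserted): the feasible cone
    is then translation-invariant along the all-ones direction and the box
    bound cannot cut it off.
    """
    d = nvars
    if not rows:
        return Fraction(1), [Fraction(0)] * d
    for r in rows:
        assert len(r) == d and sum(r) == 0, "constraint rows must be zero-sum"

    zero, one = Fraction(0), Fraction(1)
    n_struct = d + 1  # y_0..y_{d-1}, s (index d)
    cons: list[list[Fraction]] = []
    rhs: list[Fraction] = []
    for r in rows:
        cons.append([Fraction(c) for c in r] + [one])
        rhs.append(zero)
    for j in range(d):  # y_j <= 2*box
        e = [zero] * n_struct
        e[j] = one
        cons.append(e)
        rhs.append(Fraction(2 * box))
    e = [zero] * n_struct  # s <= 1
    e[d] = one
    cons.append(e)
    rhs.append(one)

    m = len(cons)
    width = n_struct + m + 1
    T: list[list[Fraction]] = []
    for i in range(m):
        row = cons[i] + [zero] * m + [rhs[i]]
        row[n_struct + i] = one
        T.append(row)
    basis = list(range(n_struct, n_struct + m))
    # reduced costs for "maximize s": start with -c
    obj = [zero] * width
    obj[d] = -one

    def current() -> tuple[Fraction, list[Fraction]]:
        sol = [zero] * n_struct
        for i, b in enumerate(basis):
            if b < n_struct:
                sol[b] = T[i][-1]
        return sol[d], [v - box for v in sol[:d]]

    while True:
        enter = next((j for j in range(width - 1) if obj[j] < 0), None)
        if enter is None:
            break
        leave = None
        best_ratio = None
        for i in range(m):
            a = T[i][enter]
            if a > 0:
                ratio = T[i][-1] / a
                if (
                    best_ratio is None
                    or ratio < best_ratio
                    or (ratio == best_ratio and basis[i] < basis[leave])
                ):
                    best_ratio, leave = ratio, i
        if leave is None:  # pragma: no cover - box bounds make the LP bounded
            raise ArithmeticError("unbounded max-slack LP")
        piv = T[leave][enter]
        T[leave] = [x / piv for x in T[leave]]
        pivot_row = T[leave]
        for i in range(m):
            if i != leave:
                f = T[i][enter]
                if f != 0:
                    T[i] = [x - f * y for x, y in zip(T[i], pivot_row)]
        f = obj[enter]
        if f != 0:
            obj = [x - f * y for x, y in zip(obj, pivot_row)]
        basis[leave] = enter
        if early_exit:
            s, x = current()
            if s > 0:
                return s, x
    return current()
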