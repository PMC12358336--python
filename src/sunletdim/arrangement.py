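"""The tie hyperplane arrangement of the 3-sunlet in reduced coordinates.

Each consistent leaf-labelling contributes a tie locus where its two tree
monomials have equal weight.  In the reduced coordinates ``(mu, nu)`` the
distinct loci are

* ``mu_0 = 0`` — crossing it flips all ``|G|`` columns ``(0, g, -g)``;
* ``mu_{g1} = nu_{g1+g2} - nu_{g2}`` for each ``g1 != 0`` and ``g2`` —
  crossing it flips the single column ``(g1, g2, .)``;

``1 + ell*(ell+1)`` hyperplanes in total.  A *chamber* is a connected
component of the complement; on a chamber the tropical Jacobian is
constant, so a chamber has a well-defined exact rank.  Chambers are in
bijection with the feasible sign vectors, enumerated here exhaustively
with exact-LP feasibility tests, pruning partial sign assignments
block-by-block in ``g1``.

Feasibility reduction: for fixed signs, each ``mu_{g1}`` must lie in the
open interval between the largest ``d = nu_{g1+g2} - nu_{g2}`` on its
"+" side and the smallest on its "-" side, so a sign vector is feasible
iff the pairwise ``nu``-difference system ``d_p < d_n`` (over all "+"/"-"
pairs within each ``g1``-block) has a strict solution — an exact
max-slack LP in ``nu`` alone.  ``mu_0`` is unconstrained, so both of its
signs are always feasible once the ``nu``-system is.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Hashable, Iterable, Optional, Sequence

import networkx as nx

from ._linalg import rank_exact
from ._lp import max_slack
from .groups import GroupElement, GroupSpec
from .jacobian import ReducedWeight, TreeAssignment, build_matrix

MU0 = "mu0"

SignVector = tuple[int, ...]  # +1 / -1 per hyperplane, in hyperplanes() order


class BudgetError(RuntimeError):
    """Exhaustive enumeration would exceed the configured budget."""


@dataclass(frozen=True)
class Hyperplane:
    """One tie hyperplane: either ``mu_0 = 0`` or
    ``mu_{g1} = nu_{g1+g2} - nu_{g2}``."""

    id: Hashable  # MU0 or (g1, g2)

    def form(self, G: GroupSpec, rw: ReducedWeight) -> Fraction:
        """Evaluate the defining linear functional; positive means the
        controlled column(s) go to T1."""
        if self.id == MU0:
            return rw.mu[G.zero()]
        g1, g2 = self.id
        return rw.mu[g1] - rw.nu[G.add(g1, g2)] + rw.nu[g2]


def hyperplanes(G: GroupSpec) -> list[Hyperplane]:
    """All ``1 + ell*(ell+1)`` hyperplanes: mu0 first, then (g1, g2)
    pairs lexicographically (g1 over nonzero elements, g2 over all)."""
    out = [Hyperplane(MU0)]
    els = G.elements()
    for g1 in els[1:]:
        for g2 in els:
            out.append(Hyperplane((g1, g2)))
    return out


def assignment_from_signs(G: GroupSpec, sv: SignVector) -> TreeAssignment:
    """The tree assignment encoded by a sign vector: +1 on a hyperplane
    sends its column(s) to T1."""
    n = G.order
    bits: list[bool] = []
    for i1 in range(n):
        for i2 in range(n):
            if i1 == 0:
                bits.append(sv[0] > 0)
            else:
                bits.append(sv[1 + (i1 - 1) * n + i2] > 0)
    return TreeAssignment(group=G, to_t1=tuple(bits))


def signs_of(G: GroupSpec, rw: ReducedWeight) -> SignVector:
    """Sign vector of a tie-free reduced weight (raises on a tie)."""
    out = []
    for h in hyperplanes(G):
        v = h.form(G, rw)
        if v == 0:
            raise ValueError(f"weight lies on hyperplane {h.id}")
        out.append(1 if v > 0 else -1)
    return tuple(out)


def _block_signs(G: GroupSpec, sv: SignVector) -> list[Sequence[int]]:
    """Split the non-mu0 part of a sign vector into per-g1 blocks."""
    n = G.order
    return [sv[1 + k * n : 1 + (k + 1) * n] for k in range(n - 1)]


def _pair_rows(
    G: GroupSpec, i1: int, plus: Iterable[int], minus: Iterable[int]
) -> list[tuple[int, ...]]:
    """nu-difference constraint rows d_p - d_n < 0 for one g1-block.

    ``d_{g1,g2} = nu_{g1+g2} - nu_{g2}``; the row for the pair (p, n) is
    the coefficient vector of ``d_p - d_n`` over nu.
    """
    n = G.order
    add = G.add_table
    rows = []
    for p in plus:
        for m in minus:
            row = [0] * n
            row[add[i1][p]] += 1
            row[p] -= 1
            row[add[i1][m]] -= 1
            row[m] += 1
            rows.append(tuple(row))
    return rows


def _nu_system(G: GroupSpec, blocks: Sequence[Sequence[int]]) -> list[tuple[int, ...]]:
    n = G.order
    rows: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    for k, signs in enumerate(blocks):
        i1 = k + 1
        plus = [i2 for i2 in range(n) if signs[i2] > 0]
        minus = [i2 for i2 in range(n) if signs[i2] < 0]
        for row in _pair_rows(G, i1, plus, minus):
            if row not in seen:
                seen.add(row)
                rows.append(row)
    return rows


def _witness_from_nu(
    G: GroupSpec, sv: SignVector, nu_vals: Sequence[Fraction]
) -> ReducedWeight:
    """Build a full interior (mu, nu) witness from a strict nu-solution:
    each mu_{g1} takes the midpoint of its feasibility interval."""
    n = G.order
    els = G.elements()
    add = G.add_table
    blocks = _block_signs(G, sv)
    mu: dict[GroupElement, Fraction] = {els[0]: Fraction(sv[0])}
    for k, signs in enumerate(blocks):
        i1 = k + 1
        d = [nu_vals[add[i1][i2]] - nu_vals[i2] for i2 in range(n)]
        plus = [d[i2] for i2 in range(n) if signs[i2] > 0]
        minus = [d[i2] for i2 in range(n) if signs[i2] < 0]
        if plus and minus:
            lo, hi = max(plus), min(minus)
            assert lo < hi, "nu solution does not separate the block"
            mu[els[i1]] = (lo + hi) / 2
        elif plus:
            mu[els[i1]] = max(plus) + 1
        else:
            mu[els[i1]] = min(minus) - 1
    nu = {els[i]: Fraction(nu_vals[i]) for i in range(n)}
    return ReducedWeight(mu=mu, nu=nu)


def is_full_dimensional(
    G: GroupSpec, sv: SignVector
) -> tuple[bool, Optional[ReducedWeight]]:
    """Exact feasibility test for a sign vector; on success also returns
    an interior witness whose assignment is verified against ``sv``."""
    rows = _nu_system(G, _block_signs(G, sv))
    s, nu_vals = max_slack(rows, G.order)
    if s <= 0:
        return False, None
    rw = _witness_from_nu(G, sv, nu_vals)
    assert signs_of(G, rw) == tuple(sv), "witness does not realize the sign vector"
    return True, rw


@dataclass(frozen=True)
class Chamber:
    """A feasible chamber: its sign vector, an exact interior witness,
    and the exact rank of its tropical Jacobian."""

    sign: SignVector
    witness: ReducedWeight
    rank: int

    def sign_map(self, G: GroupSpec) -> dict[Hashable, int]:
        return {h.id: s for h, s in zip(hyperplanes(G), self.sign)}


def enumerate_chambers(
    G: GroupSpec, force: bool = False, max_hyperplanes: int = 13
) -> list[Chamber]:
    """Exhaustively enumerate all chambers of the arrangement.

    Iterates the ``2^{ell(ell+1)}`` non-mu0 sign patterns depth-first by
    ``g1``-block, pruning partial patterns whose nu-system is already
    infeasible; each feasible pattern yields two chambers (one per mu_0
    sign).  Refuses groups with more than ``max_hyperplanes`` hyperplanes
    unless ``force`` is set (the count grows as ``2^{ell(ell+1)+1}``).
    """
    n = G.order
    n_hyp = 1 + (n - 1) * n
    if n_hyp > max_hyperplanes and not force:
        raise BudgetError(
            f"{G} has {n_hyp} hyperplanes (up to 2^{n_hyp} sign vectors); "
            "pass force=True to enumerate anyway"
        )
    patterns = list(itertools.product((1, -1), repeat=n))
    chambers: list[Chamber] = []

    def emit(blocks: list[tuple[int, ...]], nu_vals: list[Fraction]) -> None:
        flat = tuple(s for blk in blocks for s in blk)
        for mu0 in (1, -1):
            sv = (mu0,) + flat
            rw = _witness_from_nu(G, sv, nu_vals)
            ta = assignment_from_signs(G, sv)
            rank = rank_exact(build_matrix(G, ta).matrix)
            chambers.append(Chamber(sign=sv, witness=rw, rank=rank))

    def descend(k: int, blocks: list[tuple[int, ...]], rows: list[tuple[int, ...]]):
        i1 = k + 1
        for pat in patterns:
            plus = [i2 for i2 in range(n) if pat[i2] > 0]
            minus = [i2 for i2 in range(n) if pat[i2] < 0]
            new_rows = rows + _pair_rows(G, i1, plus, minus)
            s, nu_vals = max_slack(new_rows, n)
            if s <= 0:
                continue
            if k == n - 2:
                emit(blocks + [pat], nu_vals)
            else:
                descend(k + 1, blocks + [pat], new_rows)

    if n == 1:  # trivial group: only the mu0 hyperplane
        for mu0 in (1, -1):
            sv = (mu0,)
            rw = _witness_from_nu(G, sv, [Fraction(0)])
            ta = assignment_from_signs(G, sv)
            chambers.append(
                Chamber(sign=sv, witness=rw, rank=rank_exact(build_matrix(G, ta).matrix))
            )
        return chambers

    descend(0, [], [])
    return chambers


@dataclass(frozen=True)
class Census:
    """Tally of chamber ranks for one group."""

    group: GroupSpec
    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percents(self, decimals: int = 1) -> dict[int, float]:
        return {
            r: round(100 * c / self.total, decimals) for r, c in self.counts.items()
        }


def census(G: GroupSpec, chambers: Iterable[Chamber]) -> Census:
    counts: dict[int, int] = {}
    for c in chambers:
        counts[c.rank] = counts.get(c.rank, 0) + 1
    return Census(group=G, counts=dict(sorted(counts.items())))


def _facet_feasible(
    G: GroupSpec, sv: SignVector, hyp_index: int
) -> bool:
    """Does the common facet between ``sv`` and its flip at ``hyp_index``
    have nonempty relative interior?

    On the facet the flipped hyperplane holds with equality and all other
    inequalities stay strict.  For a (g1, g2') flip, ``mu_{g1}`` equals
    the pivot difference ``d_{g2'}``, so the facet is nonempty iff the
    nu-system with the pivot wedged strictly between its block's "+" and
    "-" sides (and all other blocks as usual) is strictly feasible.
    """
    n = G.order
    blocks = [list(b) for b in _block_signs(G, sv)]
    h = hyperplanes(G)[hyp_index]
    assert h.id != MU0
    g1, g2 = h.id
    k = G.index(g1) - 1
    pivot = G.index(g2)
    rows: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    for kk, signs in enumerate(blocks):
        i1 = kk + 1
        if kk == k:
            plus = [i2 for i2 in range(n) if signs[i2] > 0 and i2 != pivot]
            minus = [i2 for i2 in range(n) if signs[i2] < 0 and i2 != pivot]
            block_rows = _pair_rows(G, i1, plus, [pivot]) + _pair_rows(
                G, i1, [pivot], minus
            )
        else:
            plus = [i2 for i2 in range(n) if signs[i2] > 0]
            minus = [i2 for i2 in range(n) if signs[i2] < 0]
            block_rows = _pair_rows(G, i1, plus, minus)
        for row in block_rows:
            if row not in seen:
                seen.add(row)
                rows.append(row)
    s, _ = max_slack(rows, n)
    return s > 0


def adjacency(G: GroupSpec, chambers: Sequence[Chamber]) -> nx.Graph:
    """Chamber adjacency graph: two chambers are adjacent iff their sign
    vectors differ on exactly one hyperplane and share a full facet.

    mu0-flips always share a facet (mu_0 is otherwise unconstrained);
    single-column flips are checked with an exact facet-interior LP.
    Nodes are chamber list indices, with the chamber stored as a node
    attribute; edges carry the flipped hyperplane index.
    """
    index = {c.sign: i for i, c in enumerate(chambers)}
    graph = nx.Graph()
    for i, c in enumerate(chambers):
        graph.add_node(i, chamber=c)
    n_hyp = len(chambers[0].sign)
    for i, c in enumerate(chambers):
        for h in range(n_hyp):
            flipped = list(c.sign)
            flipped[h] = -flipped[h]
            j = index.get(tuple(flipped))
            if j is None or j < i:
                continue
            if h == 0 or _facet_feasible(G, c.sign, h):
                graph.add_edge(i, j, hyperplane=h)
    return graph


def locally_maximal_deficient(
    chambers: Sequence[Chamber], graph: nx.Graph, strict: bool = False
) -> list[int]:
    """Indices of chambers of non-maximal rank all of whose neighbours
    have rank <= their own (``strict=True`` demands strictly smaller
    neighbours instead, which is never satisfied because every chamber
    has an equal-rank mu0-flip neighbour)."""
    gmax = max(c.rank for c in chambers)
    out = []
    for i, c in enumerate(chambers):
        if c.rank >= gmax:
            continue
        neigh = [chambers[j].rank for j in graph.neighbors(i)]
        ok = all(r < c.rank for r in neigh) if strict else all(r <= c.rank for r in neigh)
        if ok:
            out.append(i)
    return out


def export_poset(
    chambers: Sequence[Chamber], graph: nx.Graph, root: int
) -> str:
    """DOT rendering of the chamber graph graded by flip distance from a
    root chamber; node labels are chamber ranks."""
    dist = nx.single_source_shortest_path_length(graph, root)
    layers: dict[int, list[int]] = {}
    for node, d in dist.items():
        layers.setdefault(d, []).append(node)
    lines = ["graph chambers {", "  rankdir=BT;"]
    for d in sorted(layers):
        members = " ".join(f"c{i}" for i in sorted(layers[d]))
        lines.append(f"  {{ rank=same; {members} }}")
    for i, c in enumerate(chambers):
        lines.append(f'  c{i} [label="{c.rank}"];')
    for i, j in sorted(graph.edges()):
        lines.append(f"  c{i} -- c{j};")
    lines.append("}")
    return "\n".join(lines) + "\n"
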