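"""Tropical Jacobians of the 3-sunlet parameterization.

A weight vector ``lambda`` on the ``6|G|`` parameters induces, for each
consistent leaf-labelling, a choice between the two tree monomials: the
labelling is *assigned* to the tree whose monomial has the smaller
``lambda``-value.  Where no tie occurs, the tropicalized map is linear
with matrix ``A_lambda`` whose column for a labelling is the exponent
vector of the chosen monomial, and

    dim V  >=  rank_Q A_lambda

so a single weight vector of high exact rank certifies a dimension lower
bound.

The comparison collapses (all shared factors cancel) to the reduced
coordinates ``mu_g = lambda6^g - lambda5^g`` and ``nu = lambda4``:
labelling ``(g1, g2, .)`` goes to ``T1`` iff
``nu_{g1+g2} - nu_{g2} < mu_{g1}`` (which for ``g1 = 0`` reads
``0 < mu_0``).  Ties are errors — on a tie the tropical map is not
differentiable and ``A_lambda`` is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np

from ._linalg import rank_exact
from .groups import GroupElement, GroupSpec
from .sunlet import LeafLabelling, ParameterIndex, consistent_labellings, exponent_matrices


class TieError(ValueError):
    """The weight vector lies on a tie hyperplane: both tree monomials of
    some labelling have equal weight, so ``A_lambda`` is undefined."""

    def __init__(self, labelling: LeafLabelling):
        self.labelling = labelling
        super().__init__(f"weight vector ties at labelling {labelling}")


@dataclass(frozen=True)
class WeightVector:
    """A full weight vector: one rational per (edge, element) parameter."""

    lam: Mapping[ParameterIndex, Fraction]


@dataclass(frozen=True)
class ReducedWeight:
    """The reduced coordinates ``(mu, nu)`` that fully
    determine all tree assignments: ``mu_g = lambda6^g - lambda5^g`` and
    ``nu_g = lambda4^g``."""

    mu: Mapping[GroupElement, Fraction]
    nu: Mapping[GroupElement, Fraction]

    def as_lists(self, G: GroupSpec) -> tuple[list[Fraction], list[Fraction]]:
        els = G.elements()
        return [self.mu[g] for g in els], [self.nu[g] for g in els]


def reduced_weight(
    G: GroupSpec, mu: Mapping[GroupElement, "Fraction | int"], nu: Mapping[GroupElement, "Fraction | int"]
) -> ReducedWeight:
    """Convenience constructor coercing values to Fractions and checking
    that both maps are total on G."""
    els = G.elements()
    return ReducedWeight(
        mu={g: Fraction(mu[g]) for g in els},
        nu={g: Fraction(nu[g]) for g in els},
    )


def reduce(G: GroupSpec, w: WeightVector) -> ReducedWeight:
    """Collapse a full weight vector to its reduced ``(mu, nu)`` pair."""
    mu = {
        g: Fraction(w.lam[ParameterIndex(6, g)]) - Fraction(w.lam[ParameterIndex(5, g)])
        for g in G.elements()
    }
    nu = {g: Fraction(w.lam[ParameterIndex(4, g)]) for g in G.elements()}
    return ReducedWeight(mu=mu, nu=nu)


@dataclass(frozen=True)
class TreeAssignment:
    """Which displayed tree each leaf-labelling is assigned to.

    ``to_t1[j]`` is True iff the j-th labelling (in the standard lex
    column order) takes its column from the T1 monomial.
    """

    group: GroupSpec
    to_t1: tuple[bool, ...]

    def choice(self, lab: LeafLabelling) -> str:
        j = self.group.index(lab.g1) * self.group.order + self.group.index(lab.g2)
        return "T1" if self.to_t1[j] else "T2"

    @property
    def t1_count(self) -> int:
        return sum(self.to_t1)

    @property
    def t2_count(self) -> int:
        return len(self.to_t1) - self.t1_count

    def signature(self) -> bytes:
        """Canonical bit-string key identifying the region."""
        return np.packbits(np.asarray(self.to_t1, dtype=np.uint8)).tobytes()


def assign(G: GroupSpec, rw: ReducedWeight) -> TreeAssignment:
    """Assign every labelling to T1 or T2 from the reduced weights.

    Raises :class:`TieError` on the first labelling whose two monomials
    have equal weight.
    """
    mu, nu = rw.as_lists(G)
    n = G.order
    add = G.add_table
    bits: list[bool] = []
    labs = consistent_labellings(G)
    for i1 in range(n):
        for i2 in range(n):
            diff = nu[add[i1][i2]] - nu[i2] - mu[i1]
            if diff == 0:
                raise TieError(labs[i1 * n + i2])
            bits.append(diff < 0)
    return TreeAssignment(group=G, to_t1=tuple(bits))


@dataclass(frozen=True)
class TropJacobian:
    """The 0/1 matrix ``A_lambda`` (rows: parameters, columns:
    labellings) together with the assignment that produced it."""

    matrix: np.ndarray
    assignment: TreeAssignment


def build_matrix(G: GroupSpec, ta: TreeAssignment) -> TropJacobian:
    """Assemble ``A_lambda`` from a tree assignment: per column the
    exponent vector of the chosen monomial."""
    M1, M2 = exponent_matrices(G)
    mask = np.asarray(ta.to_t1, dtype=bool)
    A = np.where(mask[None, :], M1, M2)
    return TropJacobian(matrix=A, assignment=ta)


def trop_rank(G: GroupSpec, rw: ReducedWeight) -> int:
    """Exact rank of ``A_lambda`` at a tie-free reduced weight."""
    return rank_exact(build_matrix(G, assign(G, rw)).matrix)
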