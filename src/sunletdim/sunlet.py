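"""The 3-sunlet parameterization in transformed (Fourier) coordinates.

A 3-sunlet is the minimal semi-directed level-1 network with a 3-cycle:
three leaf edges ``e1, e2, e3``, one undirected cycle edge ``e4``, and two
reticulation edges ``e5, e6`` directed into the reticulation vertex (the
vertex below taxon 1).  Deleting ``e6`` or ``e5`` yields the two displayed
trees ``T1`` and ``T2``.

After the Fourier transform, the model coordinate indexed by a consistent
leaf-labelling ``g = (g1, g2, g3)`` with ``g1 + g2 + g3 = 0`` is a sum of
two squarefree degree-5 monomials, one per displayed tree::

    phi(w)_g = w1^g1 w2^g2 w3^g3 w4^(g1+g2) w5^g1    (tree T1)
             + w1^g1 w2^g2 w3^g3 w4^g2      w6^g1    (tree T2)

This module builds the consistent leaf-labellings, the two exponent
vectors per labelling, numeric evaluation of the parameterization, and a
plain/Macaulay2 export of the comorphism generators.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Mapping, NamedTuple

import numpy as np

from .groups import GroupElement, GroupSpec

EDGES = (1, 2, 3, 4, 5, 6)


class ParameterIndex(NamedTuple):
    """Index of one model parameter: an (edge, group element) pair."""

    edge: int
    elem: GroupElement


class LeafLabelling(NamedTuple):
    """A consistent triple ``(g1, g2, g3)`` with ``g1 + g2 + g3 = 0``."""

    g1: GroupElement
    g2: GroupElement
    g3: GroupElement


@dataclass(frozen=True)
class ExponentVector:
    """0/1 exponent vector of one tree monomial (total degree 5)."""

    entries: Mapping[ParameterIndex, int]

    def degree(self) -> int:
        return sum(self.entries.values())


def consistent_labellings(G: GroupSpec) -> list[LeafLabelling]:
    """All ``|G|^2`` consistent leaf-labellings, lexicographic in (g1, g2)."""
    out = []
    for g1 in G.elements():
        for g2 in G.elements():
            g3 = G.neg(G.add(g1, g2))
            out.append(LeafLabelling(g1, g2, g3))
    return out


def _check_consistent(G: GroupSpec, lab: LeafLabelling) -> None:
    if G.add(G.add(lab.g1, lab.g2), lab.g3) != G.zero():
        raise ValueError(f"labelling {lab} is not consistent")


def exponent_m1(G: GroupSpec, lab: LeafLabelling) -> ExponentVector:
    """Exponent vector of the tree-T1 monomial: edges 1,2,3,4,5 with
    elements ``g1, g2, g3, g1+g2, g1``."""
    _check_consistent(G, lab)
    return ExponentVector(
        {
            ParameterIndex(1, lab.g1): 1,
            ParameterIndex(2, lab.g2): 1,
            ParameterIndex(3, lab.g3): 1,
            ParameterIndex(4, G.add(lab.g1, lab.g2)): 1,
            ParameterIndex(5, lab.g1): 1,
        }
    )


def exponent_m2(G: GroupSpec, lab: LeafLabelling) -> ExponentVector:
    """Exponent vector of the tree-T2 monomial: edges 1,2,3,4,6 with
    elements ``g1, g2, g3, g2, g1``."""
    _check_consistent(G, lab)
    return ExponentVector(
        {
            ParameterIndex(1, lab.g1): 1,
            ParameterIndex(2, lab.g2): 1,
            ParameterIndex(3, lab.g3): 1,
            ParameterIndex(4, lab.g2): 1,
            ParameterIndex(6, lab.g1): 1,
        }
    )


def row_index(G: GroupSpec, pi: ParameterIndex) -> int:
    """Row position of a parameter: edges blocked in order 1..6, elements
    in enumeration order inside each block."""
    return (pi.edge - 1) * G.order + G.index(pi.elem)


def parameter_indices(G: GroupSpec) -> list[ParameterIndex]:
    """All ``6 |G|`` parameter indices in row order."""
    return [ParameterIndex(e, g) for e in EDGES for g in G.elements()]


@lru_cache(maxsize=None)
def exponent_matrices(G: GroupSpec) -> tuple[np.ndarray, np.ndarray]:
    """Dense 0/1 exponent matrices ``(M1, M2)`` of shape
    ``(6|G|, |G|^2)``; column ``j`` is the exponent vector of the
    m1- (resp. m2-) monomial of the j-th consistent leaf-labelling."""
    n = G.order
    labs = consistent_labellings(G)
    M1 = np.zeros((6 * n, n * n), dtype=np.int8)
    M2 = np.zeros((6 * n, n * n), dtype=np.int8)
    for j, lab in enumerate(labs):
        for pi in exponent_m1(G, lab).entries:
            M1[row_index(G, pi), j] = 1
        for pi in exponent_m2(G, lab).entries:
            M2[row_index(G, pi), j] = 1
    return M1, M2


def evaluate_phi(
    G: GroupSpec, w: Mapping[ParameterIndex, Fraction]
) -> dict[LeafLabelling, Fraction]:
    """Evaluate the parameterization map at a full parameter vector ``w``.

    Each coordinate is the product of the five m1-parameters plus the
    product of the five m2-parameters.  Raises ``KeyError`` if ``w`` is
    missing an index.
    """
    for pi in parameter_indices(G):
        if pi not in w:
            raise KeyError(f"parameter {pi} missing from w")
    out: dict[LeafLabelling, Fraction] = {}
    for lab in consistent_labellings(G):
        prod1 = Fraction(1)
        for pi in exponent_m1(G, lab).entries:
            prod1 *= w[pi]
        prod2 = Fraction(1)
        for pi in exponent_m2(G, lab).entries:
            prod2 *= w[pi]
        out[lab] = prod1 + prod2
    return out


def _var(G: GroupSpec, pi: ParameterIndex) -> str:
    return f"a{pi.edge}_{G.index(pi.elem)}"


def _monomial_str(G: GroupSpec, ev: ExponentVector) -> str:
    # order factors by edge for readability
    pis = sorted(ev.entries, key=lambda pi: (pi.edge, G.index(pi.elem)))
    return "*".join(_var(G, pi) for pi in pis)


def export_comorphism(G: GroupSpec, dialect: str = "plain") -> str:
    """Export the comorphism generators (one per leaf-labelling).

    Each generator is the sum of the two tree monomials in the variables
    ``a<edge>_<element index>``.  Dialects: ``plain`` (one ``q_... = ...``
    line per labelling) and ``macaulay2`` (a ring and ideal-ready list).
    """
    if dialect not in ("plain", "macaulay2"):
        raise ValueError(f"unknown dialect {dialect!r}")
    labs = consistent_labellings(G)
    polys = [
        _monomial_str(G, exponent_m1(G, lab)) + " + " + _monomial_str(G, exponent_m2(G, lab))
        for lab in labs
    ]
    if dialect == "plain":
        lines = []
        for lab, poly in zip(labs, polys):
            name = "q_" + "".join(str(G.index(g)) for g in lab)
            lines.append(f"{name} = {poly}")
        return "\n".join(lines) + "\n"
    # macaulay2
    allvars = ",".join(_var(G, pi) for pi in parameter_indices(G))
    lines = [f"R = QQ[{allvars}];"]
    lines.append("gens3sunlet = {")
    lines.append(",\n".join("  " + p for p in polys))
    lines.append("};")
    return "\n".join(lines) + "\n"
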