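"""Closed-form dimension formulas for level-1 networks.

A level-1 (galled) semi-directed network decomposes across cut edges
into trees and sunlet networks.  For a group of odd order
``ell + 1 >= 5`` the variety of a level-1 network with ``m`` edges and
``c`` cycles has dimension ``ell*(m - c) + 1``; the 3-sunlet (six edges,
one cycle) gives the expected dimension ``5*ell + 1``, capped by the
ambient dimension ``(ell + 1)^2`` for tiny groups.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple


class Sunlet3Dimension(NamedTuple):
    """Expected dimension of the 3-sunlet model, with the ambient cap."""

    expected: int
    ambient: int
    attainable: int


def expected_dimension_sunlet3(ell: int) -> Sunlet3Dimension:
    """``5*ell + 1`` (parameter count) alongside the ambient cap
    ``(ell+1)^2`` and their minimum."""
    if ell < 1:
        raise ValueError("ell must be >= 1")
    expected = 5 * ell + 1
    ambient = (ell + 1) ** 2
    return Sunlet3Dimension(expected, ambient, min(expected, ambient))


@dataclass(frozen=True)
class NetworkCounts:
    """Edge/cycle/leaf counts of a level-1 network."""

    n_leaves: int
    m_edges: int
    c_cycles: int

    def __post_init__(self) -> None:
        if self.n_leaves < 1 or self.m_edges < self.n_leaves or self.c_cycles < 0:
            raise ValueError(f"implausible network counts {self}")


def level1_dimension(nc: NetworkCounts, ell: int) -> int:
    """Dimension ``ell*(m - c) + 1`` of a level-1 network variety.

    The formula is established for groups of odd order at least 5; a
    warning is emitted outside that range.
    """
    if (ell + 1) % 2 == 0 or ell + 1 < 5:
        warnings.warn(
            f"dimension formula is proven for odd group order >= 5, got |G| = {ell + 1}",
            stacklevel=2,
        )
    if nc.m_edges <= nc.c_cycles:
        raise ValueError("need more edges than cycles")
    return ell * (nc.m_edges - nc.c_cycles) + 1


def read_network_csv(path: "str | Path") -> NetworkCounts:
    """Count edges, cycles and leaves from a CSV edge list.

    Columns: ``child, parent, is_reticulation``.  Assumes the edge list
    describes a valid level-1 network, where each cycle contains exactly
    one reticulation vertex (a child with incoming reticulation edges).
    """
    children: list[str] = []
    parents: set[str] = set()
    retic_children: set[str] = set()
    m = 0
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() == "child":
                continue
            child, parent, is_retic = (c.strip() for c in row[:3])
            m += 1
            children.append(child)
            parents.add(parent)
            if is_retic.lower() in ("1", "true", "yes"):
                retic_children.add(child)
    leaves = {c for c in children if c not in parents}
    return NetworkCounts(n_leaves=len(leaves), m_edges=m, c_cycles=len(retic_children))
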