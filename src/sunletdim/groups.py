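"""Finite abelian groups as direct products of cyclic factors.

The state space of a group-based substitution model is a finite abelian
group ``G`` (e.g. the Klein four-group for the Kimura 3-parameter model,
or an odd-order group for recoded amino-acid alphabets).  Everything
downstream — leaf-labellings, weight vectors, tropical Jacobians — is
indexed by the elements of ``G`` in a fixed enumeration order, so the
enumeration here is deterministic: lexicographic on residue tuples, with
the identity first.

Also provided: the canonical inverse-free subset ``X`` used by the
deterministic weight-vector construction for odd-order groups, and the
injective pairing ``h : X -> G \\ X`` with ``h(g)`` avoiding ``0``,
``-g`` and ``2g`` that underpins its rank certificate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property
from itertools import permutations, product
from typing import Iterator, Mapping


class GroupParseError(ValueError):
    """Raised when a group specification string cannot be parsed."""


@dataclass(frozen=True, order=True)
class GroupElement:
    """An element of a finite abelian group: a tuple of residues.

    The element does not know its group; arithmetic lives on
    :class:`GroupSpec` so that elements stay lightweight and hashable.
    """

    residues: tuple[int, ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "(" + ",".join(str(r) for r in self.residues) + ")"


@dataclass(frozen=True)
class GroupSpec:
    """A finite abelian group ``Z/f1 x Z/f2 x ...`` given by its factors.

    ``ell + 1 = |G|`` throughout: with a trivial automorphism subgroup the
    number of orbits equals the group order, and ``ell`` is the quantity
    appearing in the expected-dimension formula ``5*ell + 1``.
    """

    factors: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.factors or any(f < 1 for f in self.factors):
            raise ValueError(f"invalid factors {self.factors!r}")

    @property
    def order(self) -> int:
        n = 1
        for f in self.factors:
            n *= f
        return n

    @property
    def ell(self) -> int:
        return self.order - 1

    @cached_property
    def _elements(self) -> tuple[GroupElement, ...]:
        return tuple(
            GroupElement(res) for res in product(*(range(f) for f in self.factors))
        )

    def elements(self) -> tuple[GroupElement, ...]:
        """All elements, lexicographic on residues, identity first."""
        return self._elements

    @cached_property
    def _index(self) -> Mapping[GroupElement, int]:
        return {g: i for i, g in enumerate(self._elements)}

    def index(self, g: GroupElement) -> int:
        return self._index[g]

    def zero(self) -> GroupElement:
        return self._elements[0]

    def add(self, a: GroupElement, b: GroupElement) -> GroupElement:
        return GroupElement(
            tuple((x + y) % f for x, y, f in zip(a.residues, b.residues, self.factors))
        )

    def neg(self, a: GroupElement) -> GroupElement:
        return GroupElement(tuple((-x) % f for x, f in zip(a.residues, self.factors)))

    def double(self, a: GroupElement) -> GroupElement:
        return self.add(a, a)

    # Index-based arithmetic (precomputed tables) for inner loops.
    @cached_property
    def add_table(self) -> list[list[int]]:
        els = self._elements
        return [[self._index[self.add(a, b)] for b in els] for a in els]

    @cached_property
    def neg_table(self) -> list[int]:
        return [self._index[self.neg(a)] for a in self._elements]

    def __str__(self) -> str:
        return "x".join(f"Z{f}" for f in self.factors)


_TOKEN = re.compile(r"^z(\d+)(?:\^(\d+))?$", re.IGNORECASE)


def parse_group(spec: str) -> GroupSpec:
    """Parse a group specification like ``"Z5"``, ``"Z2xZ2"`` or ``"Z2^3"``.

    Separators may be ``x`` or ``*`` (case-insensitive); ``Z<n>^<k>``
    repeats a cyclic factor ``k`` times.  Factors must be at least 2.
    """
    factors: list[int] = []
    for token in re.split(r"[x*]", spec.replace(" ", "")):
        m = _TOKEN.match(token)
        if not m:
            raise GroupParseError(f"cannot parse group token {token!r} in {spec!r}")
        n = int(m.group(1))
        k = int(m.group(2) or 1)
        if n < 2:
            raise GroupParseError(f"cyclic factor {n} < 2 in {spec!r}")
        if k < 1:
            raise GroupParseError(f"repeat count {k} < 1 in {spec!r}")
        factors.extend([n] * k)
    return GroupSpec(tuple(factors))


TRIVIAL_GROUP = GroupSpec((1,))


@dataclass(frozen=True)
class InverseFreeSubset:
    """A subset ``X`` of ``G`` with ``0`` excluded and ``g in X => -g not in X``.

    For odd-order groups ``|X| = t`` with ``|G| = 2t + 1`` and
    ``X, -X, {0}`` partition ``G``.  The even-order variant used by the
    modified construction additionally contains every element of order 2.
    """

    members: tuple[GroupElement, ...]

    @property
    def t(self) -> int:
        return len(self.members)

    def __contains__(self, g: GroupElement) -> bool:
        return g in set(self.members)

    def __iter__(self) -> Iterator[GroupElement]:
        return iter(self.members)


def default_X(G: GroupSpec) -> InverseFreeSubset:
    """The canonical inverse-free subset of an odd-order group.

    Scans elements in enumeration order and keeps ``g`` whenever neither
    ``g`` nor ``-g`` has been kept yet; for odd order the result has size
    ``t = (|G| - 1) / 2``.
    """
    if G.order % 2 == 0:
        raise ValueError(f"default_X requires odd group order, got |G| = {G.order}")
    if G.order < 3:
        raise ValueError("default_X requires |G| >= 3")
    chosen: list[GroupElement] = []
    seen: set[GroupElement] = set()
    for g in G.elements():
        if g == G.zero() or g in seen:
            continue
        chosen.append(g)
        seen.add(g)
        seen.add(G.neg(g))
    return InverseFreeSubset(tuple(chosen))


def even_X(G: GroupSpec) -> InverseFreeSubset:
    """The modified subset for even-order groups: all order-2 elements plus
    the first-seen member of each remaining inverse pair."""
    if G.order % 2 == 1:
        raise ValueError("even_X requires even group order")
    chosen: list[GroupElement] = []
    seen: set[GroupElement] = set()
    for g in G.elements():
        if g == G.zero() or g in seen:
            continue
        chosen.append(g)
        seen.add(g)
        seen.add(G.neg(g))  # no-op when g is self-inverse
    return InverseFreeSubset(tuple(chosen))


def pairing_map(
    G: GroupSpec, X: InverseFreeSubset
) -> dict[GroupElement, GroupElement]:
    """An injective ``h : X -> G \\ X`` with ``h(g)`` not in ``{0, -g, 2g}``.

    Exists for every inverse-free ``X`` of size ``t >= 3`` in an odd-order
    group of order ``2t + 1``.  The procedure is iterative: starting from
    the pool ``K = -X``, the first ``t - 3`` members of ``X`` greedily take
    the smallest admissible element of ``K`` (admissible: not ``-g`` and
    not ``2g``); the last three are resolved by a 3x3 matching, which is
    always solvable.
    """
    t = X.t
    if G.order != 2 * t + 1 or G.order % 2 == 0:
        raise ValueError("pairing_map requires odd |G| = 2t + 1")
    if t < 3:
        raise ValueError(f"pairing_map requires t >= 3, got t = {t}")
    members = list(X.members)
    pool = [G.neg(g) for g in members]  # K = -X, in X's order
    pool_sorted = sorted(pool, key=G.index)
    h: dict[GroupElement, GroupElement] = {}
    available = list(pool_sorted)
    for g in members[: t - 3]:
        forbidden = {G.neg(g), G.double(g)}
        pick = next(k for k in available if k not in forbidden)
        h[g] = pick
        available.remove(pick)
    last = members[t - 3 :]
    assert len(available) == 3
    for perm in permutations(available):
        if all(k not in {G.neg(g), G.double(g)} for g, k in zip(last, perm)):
            for g, k in zip(last, perm):
                h[g] = k
            break
    else:  # pragma: no cover - ruled out by the matching argument
        raise AssertionError("pairing matching failed; should be impossible")
    return h
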