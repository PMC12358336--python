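"""Shared fixtures: small groups, and cached chamber enumerations /
adjacency graphs for the groups whose arrangements are fully enumerable
at desk scale (Z3, Z4, Z2xZ2)."""

from __future__ import annotations

import pytest

import sunletdim as sd


@pytest.fixture(scope="session")
def z2():
    return sd.parse_group("Z2")


@pytest.fixture(scope="session")
def z3():
    return sd.parse_group("Z3")


@pytest.fixture(scope="session")
def z4():
    return sd.parse_group("Z4")


@pytest.fixture(scope="session")
def z5():
    return sd.parse_group("Z5")


@pytest.fixture(scope="session")
def k4():
    return sd.parse_group("Z2xZ2")


@pytest.fixture(scope="session")
def z3_chambers(z3):
    return sd.enumerate_chambers(z3)


@pytest.fixture(scope="session")
def z3_graph(z3, z3_chambers):
    return sd.adjacency(z3, z3_chambers)


@pytest.fixture(scope="session")
def z4_chambers(z4):
    return sd.enumerate_chambers(z4)


@pytest.fixture(scope="session")
def z4_graph(z4, z4_chambers):
    return sd.adjacency(z4, z4_chambers)


@pytest.fixture(scope="session")
def k4_chambers(k4):
    return sd.enumerate_chambers(k4)


@pytest.fixture(scope="session")
def k4_graph(k4, k4_chambers):
    return sd.adjacency(k4, k4_chambers)
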