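"""Tree assignments, the matrix A_lambda, and exact ranks."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

import sunletdim as sd
from sunletdim.jacobian import WeightVector
from sunletdim.sunlet import ParameterIndex, parameter_indices


def _rw(G, mu_vals, nu_vals):
    els = G.elements()
    return sd.reduced_weight(
        G,
        {g: Fraction(mu_vals[i]) for i, g in enumerate(els)},
        {g: Fraction(nu_vals[i]) for i, g in enumerate(els)},
    )


def _random_rw(G, rng):
    n = G.order
    while True:
        mu = [Fraction(int(x), 997) for x in rng.integers(-5000, 5000, n)]
        nu = [Fraction(int(x), 997) for x in rng.integers(-5000, 5000, n)]
        rw = _rw(G, mu, nu)
        try:
            sd.assign(G, rw)
        except sd.TieError:
            continue
        return rw


EX24 = _rw(sd.parse_group("Z2"), [1, -1], [3, 1])


def test_reduce_example_roundtrip(z2):
    """Any full lambda with lambda6 - lambda5 = (1, -1) and lambda4 =
    (3, 1) reduces to the worked-example values."""
    lam = {pi: Fraction(0) for pi in parameter_indices(z2)}
    e0, e1 = z2.elements()
    lam[ParameterIndex(4, e0)] = Fraction(3)
    lam[ParameterIndex(4, e1)] = Fraction(1)
    lam[ParameterIndex(5, e0)] = Fraction(2)
    lam[ParameterIndex(6, e0)] = Fraction(3)  # mu_0 = 1
    lam[ParameterIndex(5, e1)] = Fraction(5)
    lam[ParameterIndex(6, e1)] = Fraction(4)  # mu_1 = -1
    rw = sd.reduce(z2, WeightVector(lam))
    assert rw == EX24


def test_reduce_ignores_leaf_edge_weights(z2):
    lam = {pi: Fraction(0) for pi in parameter_indices(z2)}
    rw0 = sd.reduce(z2, WeightVector(lam))
    assert all(v == 0 for v in rw0.mu.values())
    assert all(v == 0 for v in rw0.nu.values())
    shifted = dict(lam)
    for g in z2.elements():
        shifted[ParameterIndex(1, g)] += Fraction(17)
    assert sd.reduce(z2, WeightVector(shifted)) == rw0


def test_assign_worked_example_z2(z2):
    ta = sd.assign(z2, EX24)
    choices = {
        tuple(g.residues[0] for g in lab): ta.choice(lab)
        for lab in sd.consistent_labellings(z2)
    }
    assert choices == {
        (0, 0, 0): "T1",
        (0, 1, 1): "T1",
        (1, 0, 1): "T1",
        (1, 1, 0): "T2",
    }


def test_assign_worked_example_z3(z3):
    ta = sd.assign(z3, _rw(z3, [-1, 7, -7], [10, 0, 2]))
    t1 = {
        tuple(g.residues[0] for g in lab)
        for lab in sd.consistent_labellings(z3)
        if ta.choice(lab) == "T1"
    }
    assert t1 == {(1, 1, 1), (1, 0, 2), (2, 0, 1)}


def test_assign_all_t1_and_tie(z3):
    ta = sd.assign(z3, _rw(z3, [1, 1, 1], [0, 0, 0]))
    assert all(ta.to_t1)
    with pytest.raises(sd.TieError) as exc:
        sd.assign(z3, _rw(z3, [0, 1, 1], [0, 0, 0]))
    assert exc.value.labelling == sd.consistent_labellings(z3)[0]


def test_build_matrix_worked_example_z2(z2):
    tj = sd.build_matrix(z2, sd.assign(z2, EX24))
    A = tj.matrix
    assert A.shape == (12, 4)
    # column (1,1,0) is the m2 exponent vector: w1^1, w2^1, w3^0, w4^1, w6^1
    col = A[:, 3]
    expect = np.zeros(12, dtype=int)
    for edge, idx in [(1, 1), (2, 1), (3, 0), (4, 1), (6, 1)]:
        expect[(edge - 1) * 2 + idx] = 1
    assert (col == expect).all()
    # the other three columns come from m1: their e6 rows vanish
    assert not A[10:12, :3].any()
    assert (A.sum(axis=0) == 5).all()


def test_build_matrix_pure_tree_assignments(z4):
    n = z4.order
    all_t1 = sd.TreeAssignment(group=z4, to_t1=(True,) * (n * n))
    all_t2 = sd.TreeAssignment(group=z4, to_t1=(False,) * (n * n))
    assert not sd.build_matrix(z4, all_t1).matrix[5 * n : 6 * n].any()  # e6 rows zero
    assert not sd.build_matrix(z4, all_t2).matrix[4 * n : 5 * n].any()  # e5 rows zero


def test_rank_exact_zero_matrix():
    assert sd.rank_exact(np.zeros((4, 6), dtype=int)) == 0
    assert sd.rank_exact([]) == 0


@given(st.data())
@settings(max_examples=40, deadline=None, derandomize=True)
def test_rank_exact_matches_sympy(data):
    """Fraction-free elimination agrees with an independent exact oracle
    on random small integer matrices."""
    m = data.draw(st.integers(2, 7))
    n = data.draw(st.integers(2, 7))
    entries = data.draw(
        st.lists(st.integers(-4, 4), min_size=m * n, max_size=m * n)
    )
    M = np.array(entries).reshape(m, n)
    assert sd.rank_exact(M) == sympy.Matrix(M.tolist()).rank()


def test_rank_mod_p_matches_exact_on_jacobians(z4):
    rng = np.random.default_rng(11)
    n = z4.order
    for _ in range(20):
        bits = tuple(bool(b) for b in rng.integers(0, 2, n * n))
        A = sd.build_matrix(z4, sd.TreeAssignment(group=z4, to_t1=bits)).matrix
        assert sd.rank_mod_p(A) == sd.rank_exact(A)


def test_pure_tree_rank_is_3ell_plus_1(z5):
    """All-one-tree chambers have the 3-star tree rank 3*ell + 1."""
    rw = _rw(z5, [1] * 5, [0] * 5)
    assert sd.trop_rank(z5, rw) == 3 * z5.ell + 1  # = 13
    rw2 = _rw(z5, [-1] * 5, [0] * 5)
    assert sd.trop_rank(z5, rw2) == 13


def test_trop_rank_examples(z2, z3):
    ex24 = sd.build_matrix(z2, sd.assign(z2, EX24)).matrix
    assert sd.rank_exact(ex24) == sympy.Matrix(ex24.tolist()).rank()
    ex33 = sd.build_matrix(z3, sd.assign(z3, _rw(z3, [-1, 7, -7], [10, 0, 2]))).matrix
    assert sd.rank_exact(ex33) == sympy.Matrix(ex33.tolist()).rank()
    # trivial group: single column of five ones
    G = sd.TRIVIAL_GROUP
    rw = sd.reduced_weight(G, {G.zero(): 1}, {G.zero(): 0})
    assert sd.trop_rank(G, rw) == 1


def test_row_identity_r1_equals_r5_plus_r6():
    """For every assignment the leaf-1 row block is the sum of the two
    reticulation row blocks, capping the rank at 5(ell+1)."""
    rng = np.random.default_rng(5)
    for name in ("Z3", "Z5", "Z2xZ2"):
        G = sd.parse_group(name)
        n = G.order
        for _ in range(10):
            bits = tuple(bool(b) for b in rng.integers(0, 2, n * n))
            A = sd.build_matrix(G, sd.TreeAssignment(group=G, to_t1=bits)).matrix
            assert (A[0:n] == A[4 * n : 5 * n] + A[5 * n : 6 * n]).all()
            assert sd.rank_exact(A) <= 5 * n


def test_rank_bounds_random_weights():
    rng = np.random.default_rng(6)
    for name in ("Z3", "Z4", "Z5", "Z2xZ2"):
        G = sd.parse_group(name)
        cap = min(5 * G.ell + 1, G.order**2)
        for _ in range(5):
            assert 3 * G.ell + 1 <= sd.trop_rank(G, _random_rw(G, rng)) <= cap


def test_mu0_negation_preserves_rank():
    """Flipping the sign of mu_0 swaps the w5^0 / w6^0 rows of A_lambda
    and therefore never changes the rank."""
    rng = np.random.default_rng(7)
    for name in ("Z3", "Z4", "Z5"):
        G = sd.parse_group(name)
        for _ in range(5):
            rw = _random_rw(G, rng)
            flipped = sd.ReducedWeight(
                mu={**rw.mu, G.zero(): -rw.mu[G.zero()]}, nu=rw.nu
            )
            assert sd.trop_rank(G, rw) == sd.trop_rank(G, flipped)


def test_assignment_implication_lemma():
    """If (g,h,.) is the unique T1 labelling in g's block and some
    (-g,k,.) is assigned T2, then (-g, g+h, -h) is assigned T2."""
    rng = np.random.default_rng(8)
    for name in ("Z3", "Z5", "Z7", "Z9", "Z2xZ2", "Z6", "Z8", "Z2xZ4"):
        G = sd.parse_group(name)
        n = G.order
        for _ in range(8):
            rw = _random_rw(G, rng)
            ta = sd.assign(G, rw)

            def to_t1(a, b):
                return ta.to_t1[G.index(a) * n + G.index(b)]

            for g in G.elements():
                if g == G.zero() or g == G.neg(g):
                    continue
                t1_hs = [h for h in G.elements() if to_t1(g, h)]
                if len(t1_hs) != 1:
                    continue
                h = t1_hs[0]
                neg_g = G.neg(g)
                if any(not to_t1(neg_g, k) for k in G.elements()):
                    assert not to_t1(neg_g, G.add(g, h))
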