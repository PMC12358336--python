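"""The tie hyperplane arrangement: chambers, censuses, adjacency."""

from __future__ import annotations

import itertools
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

import sunletdim as sd
from sunletdim.arrangement import MU0


def _rw(G, mu_vals, nu_vals):
    els = G.elements()
    return sd.reduced_weight(
        G,
        {g: Fraction(v) for g, v in zip(els, mu_vals)},
        {g: Fraction(v) for g, v in zip(els, nu_vals)},
    )


@pytest.mark.parametrize("text, count", [("Z2", 3), ("Z3", 7), ("Z4", 13), ("Z2xZ2", 13)])
def test_hyperplane_count(text, count):
    G = sd.parse_group(text)
    hyps = sd.hyperplanes(G)
    assert len(hyps) == count == 1 + G.ell * G.order
    assert hyps[0].id == MU0


def test_hyperplane_forms_pairwise_distinct(z4):
    """Evaluate each form on the (mu, nu) coordinate basis: no two
    hyperplanes define the same functional."""
    els = z4.elements()
    vectors = []
    for h in sd.hyperplanes(z4):
        coeffs = []
        for kind in ("mu", "nu"):
            for g in els:
                mu = {e: Fraction(0) for e in els}
                nu = {e: Fraction(0) for e in els}
                (mu if kind == "mu" else nu)[g] = Fraction(1)
                coeffs.append(h.form(z4, sd.ReducedWeight(mu=mu, nu=nu)))
        vectors.append(tuple(coeffs))
    assert len(set(vectors)) == len(vectors)


def test_assignment_from_signs_extremes(z3):
    n_hyp = 1 + z3.ell * z3.order
    assert all(sd.assignment_from_signs(z3, (1,) * n_hyp).to_t1)
    assert not any(sd.assignment_from_signs(z3, (-1,) * n_hyp).to_t1)


def test_assignment_from_signs_consistent_with_assign():
    rng = np.random.default_rng(4)
    for name in ("Z3", "Z4", "Z2xZ2"):
        G = sd.parse_group(name)
        for _ in range(10):
            mu = [Fraction(int(x), 499) for x in rng.integers(-2000, 2000, G.order)]
            nu = [Fraction(int(x), 499) for x in rng.integers(-2000, 2000, G.order)]
            rw = _rw(G, mu, nu)
            try:
                ta = sd.assign(G, rw)
            except sd.TieError:
                continue
            assert sd.assignment_from_signs(G, sd.signs_of(G, rw)).to_t1 == ta.to_t1


def test_z2_all_sign_vectors_feasible(z2):
    for sv in itertools.product((1, -1), repeat=3):
        ok, witness = sd.is_full_dimensional(z2, sv)
        assert ok
        assert sd.signs_of(z2, witness) == sv


def test_z3_all_plus_realizes_all_t1(z3):
    ok, witness = sd.is_full_dimensional(z3, (1,) * 7)
    assert ok
    assert all(sd.assign(z3, witness).to_t1)


def test_z3_feasible_sign_vector_count(z3):
    """Direct scan of all 2^7 sign vectors: 92 are feasible."""
    count = sum(
        sd.is_full_dimensional(z3, sv)[0]
        for sv in itertools.product((1, -1), repeat=7)
    )
    assert count == 92


def test_enumerate_chambers_z2_and_budget_guard(z2, z5):
    assert len(sd.enumerate_chambers(z2)) == 8  # upper bound 2^3 attained
    with pytest.raises(sd.BudgetError):
        sd.enumerate_chambers(z5)


def test_z3_census(z3, z3_chambers):
    c = sd.census(z3, z3_chambers)
    assert c.counts == {7: 4, 8: 24, 9: 64}
    assert c.total == 92
    assert c.percents(1) == {7: 4.3, 8: 26.1, 9: 69.6}
    # chambers are unique by sign vector and witnesses lie inside
    signs = {ch.sign for ch in z3_chambers}
    assert len(signs) == 92
    for ch in z3_chambers[:10]:
        assert sd.signs_of(z3, ch.witness) == ch.sign


def test_exactly_four_minimal_rank_chambers(z3, z3_chambers):
    minimal = [c for c in z3_chambers if c.rank == 3 * z3.ell + 1]
    assert len(minimal) == 4
    # they are the four all-one-tree assignments (up to the mu0 flip)
    for c in minimal:
        body = set(c.sign[1:])
        assert len(body) == 1


def test_adjacency_rank_steps(z3, z3_chambers, z3_graph):
    """Across the mu0 hyperplane the rank is preserved; across any facet
    it changes by at most one; every chamber has an equal-rank
    neighbour."""
    for i, j, data in z3_graph.edges(data=True):
        ri, rj = z3_chambers[i].rank, z3_chambers[j].rank
        assert abs(ri - rj) <= 1
        if data["hyperplane"] == 0:
            assert ri == rj
    for i in range(len(z3_chambers)):
        assert any(
            z3_chambers[j].rank == z3_chambers[i].rank for j in z3_graph.neighbors(i)
        )


def test_mu0_flip_partner_always_exists_and_preserves_rank(z3, z3_chambers):
    index = {c.sign: c for c in z3_chambers}
    for c in z3_chambers:
        partner = index[(-c.sign[0],) + c.sign[1:]]
        assert partner.rank == c.rank


def test_shortest_path_between_pure_tree_chambers(z3, z3_chambers, z3_graph):
    all_t1 = next(i for i, c in enumerate(z3_chambers) if all(s == 1 for s in c.sign))
    all_t2 = next(i for i, c in enumerate(z3_chambers) if all(s == -1 for s in c.sign))
    assert nx.shortest_path_length(z3_graph, all_t1, all_t2) == 7


def test_locally_maximal_z3(z3_chambers, z3_graph):
    assert sd.locally_maximal_deficient(z3_chambers, z3_graph) == []
    assert sd.locally_maximal_deficient(z3_chambers, z3_graph, strict=True) == []


def test_export_poset_z3(z3, z3_chambers, z3_graph):
    root = next(i for i, c in enumerate(z3_chambers) if all(s == 1 for s in c.sign))
    dot = sd.export_poset(z3_chambers, z3_graph, root)
    assert dot.count("label=") == 92
    # the deepest BFS layer is at flip distance 7 (the all-T2 chamber)
    layers = [line for line in dot.splitlines() if "rank=same" in line]
    assert len(layers) == 8
    ranks = sorted(
        int(seg.split('"')[1]) for seg in dot.splitlines() if "label=" in seg
    )
    assert ranks == [7] * 4 + [8] * 24 + [9] * 64


def test_single_chamber_poset():
    G = sd.TRIVIAL_GROUP
    chambers = sd.enumerate_chambers(G)
    assert len(chambers) == 2
    graph = sd.adjacency(G, chambers)
    dot = sd.export_poset(chambers[:1], nx.Graph([(0, 0)]), 0)
    assert "c0" in dot and "--" not in dot.replace("c0 -- c0", "")
    assert graph.number_of_edges() == 1  # the two chambers meet at mu0 = 0


def test_sampled_census_matches_enumeration(z3, z3_chambers):
    """Dense random sampling with deduplication rediscovers exactly the
    enumerated chambers, with identical ranks per region."""
    rep = sd.sample_regions(z3, 100_000, seed=3)
    by_sig = {
        sd.assignment_from_signs(z3, c.sign).signature(): c.rank for c in z3_chambers
    }
    assert set(rep.regions_seen) == set(by_sig)
    for sig, rank in rep.regions_seen.items():
        assert rank == by_sig[sig]
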