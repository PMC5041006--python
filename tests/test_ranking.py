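"""Kendall tau distance, Kemeny objective, sorting heuristic, exact oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gfex.matrix import GeneFamilyMatrix
from gfex.ranking import (
    PartialRanking,
    exact_kemeny,
    kemeny_objective,
    kendall_tau_distance,
    partial_rankings_from_matrix,
    partial_tau_disagreements,
    s_rank,
)

from conftest import random_matrix


# -- Kendall tau distance --------------------------------------------------

def test_tau_distance_examples():
    assert kendall_tau_distance("abcd", "abcd") == 0
    assert kendall_tau_distance("abcd", "dcba") == 6
    assert kendall_tau_distance("abcd", "acbd") == 1
    with pytest.raises(ValueError, match="same element set"):
        kendall_tau_distance("abc", "abd")


@st.composite
def permutation_triples(draw):
    n = draw(st.integers(2, 7))
    items = [f"e{i}" for i in range(n)]
    perms = [draw(st.permutations(items)) for _ in range(3)]
    return perms


@given(permutation_triples())
def test_tau_distance_metric_axioms(perms):
    a, b, c = perms
    dab = kendall_tau_distance(a, b)
    assert dab == kendall_tau_distance(b, a)
    assert (dab == 0) == (list(a) == list(b))
    assert 0 <= dab <= len(a) * (len(a) - 1) // 2
    assert dab <= kendall_tau_distance(a, c) + kendall_tau_distance(c, b)


# -- partial disagreements and the objective -------------------------------

def test_partial_disagreements_worked_columns(fictional_matrix):
    prs = {pr.cog_id: pr for pr in partial_rankings_from_matrix(fictional_matrix)}
    # c5 counts {A:16, B:4, C:6}: pairs A-B and A-C contradict the order A<B<C
    assert partial_tau_disagreements(["A", "B", "C"], prs["c5"]) == 2
    # c4 counts {A:1, B:2, C:6} agree everywhere
    assert partial_tau_disagreements(["A", "B", "C"], prs["c4"]) == 0
    single = PartialRanking("x", {"A": 3})
    assert partial_tau_disagreements(["A", "B", "C"], single) == 0
    with pytest.raises(ValueError, match="does not cover"):
        partial_tau_disagreements(["A", "B"], prs["c5"])


def test_kemeny_objective_of_fictional_order(fictional_matrix):
    assert kemeny_objective(["A", "B", "C"], fictional_matrix) == 3
    with pytest.raises(ValueError, match="permutation"):
        kemeny_objective(["A", "B"], fictional_matrix)


def test_objective_zero_cases():
    # disjoint single-member COGs constrain nothing
    m = GeneFamilyMatrix(["x", "y"], ["c1", "c2"], np.array([[2, 0], [0, 3]]))
    for order in (["x", "y"], ["y", "x"]):
        assert kemeny_objective(order, m) == 0
    # one COG ranking all genomes strictly has zero cost on its own order
    m2 = GeneFamilyMatrix(["x", "y", "z"], ["c1"], np.array([[1], [2], [3]]))
    assert kemeny_objective(["x", "y", "z"], m2) == 0


@given(seed=st.integers(0, 2_000))
def test_objective_matches_per_cog_sum_and_is_relabel_invariant(seed):
    m = random_matrix(seed, n_genomes=5, n_cogs=7)
    rng = np.random.default_rng(seed)
    order = [m.genome_ids[i] for i in rng.permutation(5)]
    by_sum = sum(
        partial_tau_disagreements(order, pr) for pr in partial_rankings_from_matrix(m)
    )
    assert kemeny_objective(order, m) == by_sum
    # permuting COG columns and renaming them changes nothing
    perm = rng.permutation(m.n_cogs)
    shuffled = GeneFamilyMatrix(
        m.genome_ids, [f"renamed{j}" for j in range(m.n_cogs)], m.counts[:, perm]
    )
    assert kemeny_objective(order, shuffled) == by_sum


# -- exact solver ----------------------------------------------------------

def test_exact_kemeny_fictional_unique_minimum(fictional_matrix):
    order, obj = exact_kemeny(fictional_matrix)
    assert (order, obj) == (["A", "B", "C"], 3)
    # verified unique: every other permutation costs strictly more
    others = [
        kemeny_objective(list(p), fictional_matrix)
        for p in itertools.permutations("ABC")
        if list(p) != ["A", "B", "C"]
    ]
    assert min(others) > 3


def test_exact_kemeny_single_strict_cog():
    m = GeneFamilyMatrix(["x", "y", "z"], ["c1"], np.array([[3], [1], [2]]))
    assert exact_kemeny(m) == (["y", "z", "x"], 0)


def test_exact_kemeny_refuses_large_instances():
    m = random_matrix(0, n_genomes=6, n_cogs=4)
    with pytest.raises(ValueError, match="refused"):
        exact_kemeny(m, max_n=5)


# -- sorting heuristic -----------------------------------------------------

def test_s_rank_fictional_consensus(fictional_matrix):
    for seed in (0, 17, 123):
        r = s_rank(fictional_matrix, n_restarts=10, seed=seed)
        assert r.consensus_order == ["A", "B", "C"]
        assert r.objective == 3
        assert [r.consensus_rank(g) for g in "ABC"] == [1, 2, 3]


def test_s_rank_single_genome():
    m = GeneFamilyMatrix(["only"], ["c1"], np.array([[2]]))
    r = s_rank(m, seed=4)
    assert r.mean_rank["only"] == 1.0 and r.rank_sd["only"] == 0.0


def test_s_rank_identical_rows_average_to_half_ranks():
    m = GeneFamilyMatrix(["u", "v"], ["c1", "c2"], np.array([[2, 3], [2, 3]]))
    r = s_rank(m, n_restarts=200, seed=11)
    # no swap ever fires, so each order is decided by the initial shuffle
    assert r.mean_rank["u"] == pytest.approx(1.5, abs=0.15)
    assert r.mean_rank["v"] == pytest.approx(1.5, abs=0.15)


def test_s_rank_seed_determinism(fictional_matrix):
    a = s_rank(fictional_matrix, n_restarts=10, seed=99)
    b = s_rank(fictional_matrix, n_restarts=10, seed=99)
    assert a == b
    c = s_rank(fictional_matrix, n_restarts=10, seed=100)
    assert a.seed != c.seed


def test_mean_ranks_lie_in_range(fictional_matrix):
    r = s_rank(fictional_matrix, seed=3)
    assert all(1 <= v <= 3 for v in r.mean_rank.values())


def test_exact_oracle_dominates_heuristic_on_random_instances():
    for seed in range(100):
        m = random_matrix(seed, n_genomes=6, n_cogs=8)
        exact_order, exact_obj = exact_kemeny(m)
        heur = s_rank(m, n_restarts=5, seed=seed)
        assert exact_obj == kemeny_objective(exact_order, m)
        assert exact_obj <= heur.objective


def test_heuristic_is_exact_when_majority_relation_is_total_order():
    # one COG ranks everyone strictly: the majority relation is that order
    m = GeneFamilyMatrix(
        ["p", "q", "r", "s"], ["c1"], np.array([[4], [2], [1], [3]])
    )
    r = s_rank(m, n_restarts=5, seed=0)
    assert r.consensus_order == ["r", "q", "s", "p"]
    assert r.objective == exact_kemeny(m)[1] == 0


def test_rank_sd_small_under_strong_planted_order():
    # genome i holds roughly i+1 copies everywhere: nearly every pairwise
    # majority points the same way, so restarts should agree closely
    rng = np.random.default_rng(2)
    n, k = 30, 120
    counts = np.arange(1, n + 1)[:, None] + rng.integers(0, 2, size=(n, k))
    m = GeneFamilyMatrix([f"g{i:02d}" for i in range(n)], [f"c{j}" for j in range(k)], counts)
    r = s_rank(m, n_restarts=10, seed=2)
    median_sd = float(np.median(list(r.rank_sd.values())))
    assert median_sd < 0.05 * n
    # and the consensus essentially recovers the planted order
    planted = [f"g{i:02d}" for i in range(n)]
    assert kendall_tau_distance(r.consensus_order, planted) < 0.05 * n * (n - 1) / 2
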