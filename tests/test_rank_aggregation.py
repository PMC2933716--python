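"""Distances, the weighted objective, and the three minimizers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rankbag as rb
from rankbag.rank_aggregation import _all_perm_ranks

from conftest import random_problem


def brute_oracle(problem):
    """Independent exhaustive minimizer: plain itertools enumeration."""
    best, best_phi = None, np.inf
    for perm in itertools.permutations(problem.items):
        phi = rb.objective_phi(perm, problem)
        if phi < best_phi:
            best, best_phi = perm, phi
    return best, best_phi


@pytest.mark.parametrize(
    "l1, l2, expected",
    [
        ("ABC", "ABC", 0),
        ("ABC", "CBA", 4),
        ("ABCD", "BADC", 4),
    ],
)
def test_footrule_examples(l1, l2, expected):
    assert rb.spearman_footrule(list(l1), list(l2)) == expected
    assert rb.spearman_footrule(list(l2), list(l1)) == expected


@pytest.mark.parametrize(
    "l1, l2, expected",
    [
        ("ABC", "ABC", 0),
        ("ABC", "CBA", 3),
        ("ABC", "BAC", 1),
    ],
)
def test_kendall_examples(l1, l2, expected):
    assert rb.kendall_tau_distance(list(l1), list(l2)) == expected
    assert rb.kendall_tau_distance(list(l2), list(l1)) == expected


def test_mismatched_item_sets_rejected():
    with pytest.raises(rb.IncomparableListsError):
        rb.spearman_footrule("ABC", "ABD")
    with pytest.raises(rb.IncomparableListsError):
        rb.kendall_tau_distance("ABC", "AB")
    with pytest.raises(rb.IncomparableListsError):
        rb.objective_phi("ABD", rb.AggregationProblem((("A", "B", "C"),)))


def test_objective_phi_weighted_sum():
    problem = rb.AggregationProblem((("A", "B", "C"), ("C", "B", "A")), (1, 1))
    assert rb.objective_phi(("A", "B", "C"), problem) == 4.0
    problem2 = rb.AggregationProblem((("A", "B", "C"), ("C", "B", "A")), (2, 1))
    assert rb.objective_phi(("C", "B", "A"), problem2) == 8.0
    # identical lists, any weights: zero at the common ordering
    problem3 = rb.AggregationProblem((("A", "B"), ("A", "B")), (0.3, 7.0))
    assert rb.objective_phi(("A", "B"), problem3) == 0.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(2, 6), st.integers(0, 10_000))
def test_distances_are_metrics(m, seed):
    """Nonnegativity, identity, symmetry, triangle inequality on random triples."""
    rng = np.random.default_rng(seed)
    items = list(range(m))
    a, b, c = (tuple(rng.permutation(items)) for _ in range(3))
    for dist in (rb.spearman_footrule, rb.kendall_tau_distance):
        assert dist(a, a) == 0
        dab = dist(a, b)
        assert dab >= 0 and (dab > 0) == (a != b)
        assert dab == dist(b, a)
        assert dist(a, c) <= dab + dist(b, c)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(2, 6), st.integers(0, 10_000))
def test_diaconis_graham_inequality(m, seed):
    """kendall <= footrule <= 2 * kendall on random pairs."""
    rng = np.random.default_rng(seed)
    items = list(range(m))
    a, b = tuple(rng.permutation(items)), tuple(rng.permutation(items))
    kt = rb.kendall_tau_distance(a, b)
    fr = rb.spearman_footrule(a, b)
    assert kt <= fr <= 2 * kt


def test_kendall_maximum_on_reversal():
    m = 6
    fwd = tuple(range(m))
    assert rb.kendall_tau_distance(fwd, fwd[::-1]) == m * (m - 1) // 2


def test_phi_invariant_under_relabeling(rng):
    problem = random_problem(rng, m=5, k=3)
    mapping = {x: f"alg_{x}" for x in problem.items}
    relabeled = rb.AggregationProblem(
        tuple(tuple(mapping[x] for x in l) for l in problem.lists),
        problem.weights,
        problem.distance,
    )
    for _ in range(5):
        delta = tuple(rng.permutation(problem.items))
        assert rb.objective_phi(delta, problem) == rb.objective_phi(
            tuple(mapping[x] for x in delta), relabeled
        )


class TestBruteForce:
    def test_single_list_returns_itself(self):
        problem = rb.AggregationProblem((("B", "A", "C"),))
        res = rb.aggregate_brute_force(problem)
        assert res.best_order == ("B", "A", "C")
        assert res.objective == 0.0

    def test_symmetric_tie_breaks_lexicographically(self):
        problem = rb.AggregationProblem((("A", "B", "C"), ("C", "B", "A")), (1, 1))
        res = rb.aggregate_brute_force(problem)
        assert res.objective == 4.0
        # several orderings attain 4; the lexicographically first wins
        ties = [
            p
            for p in itertools.permutations("ABC")
            if rb.objective_phi(p, problem) == 4.0
        ]
        assert res.best_order == min(ties)

    def test_majority_list_wins_kendall(self):
        problem = rb.AggregationProblem(
            (("A", "B"), ("A", "B"), ("B", "A")), (1, 1, 1), "kendall"
        )
        res = rb.aggregate_brute_force(problem)
        assert res.best_order == ("A", "B")
        assert res.objective == 1.0

    def test_matches_independent_enumeration(self, rng):
        for _ in range(25):
            problem = random_problem(rng)
            res = rb.aggregate_brute_force(problem)
            _, oracle_phi = brute_oracle(problem)
            assert res.objective == pytest.approx(oracle_phi)
            assert rb.objective_phi(res.best_order, problem) == pytest.approx(
                res.objective
            )

    def test_cap_enforced(self):
        items = [chr(65 + i) for i in range(9)]
        problem = rb.AggregationProblem((tuple(items),))
        with pytest.raises(rb.RankAggregationError, match="brute force"):
            rb.aggregate_brute_force(problem)

    def test_lexicographic_permutation_table(self):
        seqs, ranks = _all_perm_ranks(3)
        assert [tuple(s) for s in seqs[:2]] == [(0, 1, 2), (0, 2, 1)]
        assert (np.sort(ranks, axis=1) == np.arange(3)).all()


@pytest.mark.parametrize("method", ["cross_entropy", "genetic"])
class TestStochasticOptimizers:
    def test_single_list_optimum(self, method):
        problem = rb.AggregationProblem((("X", "Y", "Z"),))
        res = rb.aggregate(problem, method, seed=0)
        assert res.best_order == ("X", "Y", "Z")
        assert res.objective == 0.0

    def test_attains_brute_force_minimum(self, method, rng):
        """20 random small problems: heuristic equals the exact optimum."""
        for _ in range(20):
            problem = random_problem(rng)
            exact = rb.aggregate_brute_force(problem)
            res = rb.aggregate(problem, method, seed=int(rng.integers(2**31)))
            assert res.objective == pytest.approx(exact.objective)

    def test_seed_determinism(self, method):
        problem = rb.AggregationProblem(
            (("A", "B", "C", "D"), ("D", "C", "B", "A"), ("B", "A", "D", "C"))
        )
        r1 = rb.aggregate(problem, method, seed=42)
        r2 = rb.aggregate(problem, method, seed=42)
        assert r1 == r2


def test_best_algorithm_weighting():
    problem = rb.AggregationProblem(
        (("A", "B", "C"), ("C", "B", "A")), (10, 1), "footrule"
    )
    assert rb.best_algorithm(problem) == "A"


def test_best_algorithm_unanimous_leader(rng):
    lists = tuple(("X",) + tuple(rng.permutation(["Y", "Z", "W"])) for _ in range(3))
    assert rb.best_algorithm(rb.AggregationProblem(lists)) == "X"


def test_best_algorithm_symmetric_tie_documented():
    # perfectly symmetric problem: the documented tie-break is lexicographic
    problem = rb.AggregationProblem((("A", "B"), ("B", "A")))
    assert rb.best_algorithm(problem) == "A"


def test_invalid_problems_rejected():
    with pytest.raises(rb.RankAggregationError):
        rb.AggregationProblem(())
    with pytest.raises(rb.RankAggregationError):
        rb.AggregationProblem((("A", "B"),), (1.0, 2.0))
    with pytest.raises(rb.RankAggregationError):
        rb.AggregationProblem((("A", "B"),), (-1.0,))
    with pytest.raises(rb.RankAggregationError):
        rb.AggregationProblem((("A", "B"),), distance="euclid")
    with pytest.raises(rb.IncomparableListsError):
        rb.AggregationProblem((("A", "A"),))
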