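"""Weighted rank aggregation of ordered lists.

Given K ordered lists ``L_1, ..., L_K`` of the same M items (here: classifier
identifiers ranked best-first by K different performance measures) and positive
weights ``w_1, ..., w_K``, the consensus ordering is the permutation ``delta``
minimizing the weighted objective

    Phi(delta) = sum_i w_i * d(delta, L_i),

where ``d`` is either the Spearman footrule distance (sum of absolute rank
displacements) or the Kendall tau distance (number of discordantly ordered
item pairs).  Both distances are metrics on the permutation group and are used
unnormalized; all scaling lives in the weights.

Three minimizers are provided: exhaustive enumeration (exact, for M up to a
small cap), a cross-entropy Monte-Carlo search, and a genetic algorithm with
order crossover.  The stochastic optimizers are fully reproducible given a
seed and always consider the input lists themselves as candidates, so for
K = 1 they return ``L_1`` with objective 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Hashable, Sequence

import numpy as np

__all__ = [
    "AggregationProblem",
    "AggregationResult",
    "IncomparableListsError",
    "RankAggregationError",
    "spearman_footrule",
    "kendall_tau_distance",
    "objective_phi",
    "aggregate_brute_force",
    "aggregate_cross_entropy",
    "aggregate_genetic",
    "aggregate",
    "best_algorithm",
]

BRUTE_FORCE_CAP = 8  # 8! = 40320 orderings, enumerated vectorized in ~ms


class RankAggregationError(ValueError):
    """Invalid rank-aggregation input."""


class IncomparableListsError(RankAggregationError):
    """Two lists are not permutations of the same identifier set."""


def _check_comparable(l1: Sequence[Hashable], l2: Sequence[Hashable]) -> None:
    s1, s2 = set(l1), set(l2)
    if len(s1) != len(l1) or len(s2) != len(l2):
        raise IncomparableListsError("ranked lists must contain distinct items")
    if s1 != s2:
        raise IncomparableListsError(
            f"lists are over different item sets: {sorted(map(str, s1 ^ s2))}"
        )


def _rank_vector(lst: Sequence[Hashable], index: dict) -> np.ndarray:
    """0-based position of each item (in ``index`` order) within ``lst``."""
    r = np.empty(len(lst), dtype=np.int64)
    for pos, item in enumerate(lst):
        r[index[item]] = pos
    return r


def spearman_footrule(l1: Sequence[Hashable], l2: Sequence[Hashable]) -> int:
    """Sum over items of the absolute difference in rank between two lists.

    Ranges from 0 (identical orderings) to M^2/2 rounded down to even
    structure for a full reversal.
    """
    _check_comparable(l1, l2)
    index = {item: i for i, item in enumerate(l1)}
    r2 = _rank_vector(l2, index)
    return int(np.abs(r2 - np.arange(len(l1))).sum())


def kendall_tau_distance(l1: Sequence[Hashable], l2: Sequence[Hashable]) -> int:
    """Number of item pairs ordered discordantly between two lists.

    0 for identical lists, M(M-1)/2 for a full reversal.
    """
    _check_comparable(l1, l2)
    index = {item: i for i, item in enumerate(l1)}
    r2 = _rank_vector(l2, index)
    # pair (i, j) with i before j in l1 is discordant iff j before i in l2
    m = len(l1)
    disc = 0
    for i in range(m):
        disc += int(np.sum(r2[i + 1 :] < r2[i]))
    return disc


@dataclass(frozen=True)
class AggregationProblem:
    """K ordered lists over the same M items, with positive weights.

    Parameters
    ----------
    lists : sequence of ranked lists, each best-first.
    weights : one positive weight per list; defaults to equal weights.
    distance : "footrule" or "kendall".
    """

    lists: tuple
    weights: tuple = ()
    distance: str = "footrule"

    def __post_init__(self):
        lists = tuple(tuple(l) for l in self.lists)
        object.__setattr__(self, "lists", lists)
        if not lists:
            raise RankAggregationError("need at least one ranked list")
        for l in lists[1:]:
            _check_comparable(lists[0], l)
        if len(set(lists[0])) != len(lists[0]):
            raise IncomparableListsError("ranked lists must contain distinct items")
        weights = tuple(float(w) for w in self.weights) or tuple(
            1.0 for _ in lists
        )
        if len(weights) != len(lists):
            raise RankAggregationError(
                f"got {len(weights)} weights for {len(lists)} lists"
            )
        if any(w <= 0 for w in weights):
            raise RankAggregationError("weights must be positive")
        object.__setattr__(self, "weights", weights)
        if self.distance not in ("footrule", "kendall"):
            raise RankAggregationError(f"unknown distance {self.distance!r}")

    @property
    def n_items(self) -> int:
        return len(self.lists[0])

    @property
    def items(self) -> tuple:
        """Items in sorted order (identifiers must be mutually orderable)."""
        return tuple(sorted(self.lists[0]))


@dataclass(frozen=True)
class AggregationResult:
    best_order: tuple
    objective: float
    method: str
    converged: bool = True


def objective_phi(delta: Sequence[Hashable], problem: AggregationProblem) -> float:
    """Weighted sum of distances from ``delta`` to each input list."""
    _check_comparable(delta, problem.lists[0])
    dist = spearman_footrule if problem.distance == "footrule" else kendall_tau_distance
    return float(
        sum(w * dist(delta, l) for w, l in zip(problem.weights, problem.lists))
    )


# ---------------------------------------------------------------------------
# vectorized Phi evaluation over batches of candidate orderings
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _all_perm_ranks(m: int):
    """All m! permutations (lexicographic by item-index sequence) as rank rows.

    Returns (seqs, ranks): seqs[k] is the k-th permutation as a sequence of
    item indices; ranks[k, j] is the position of item j in that permutation.
    """
    seqs = np.array(list(itertools.permutations(range(m))), dtype=np.int16)
    ranks = np.argsort(seqs, axis=1).astype(np.int16)
    return seqs, ranks


@lru_cache(maxsize=8)
def _pair_index(m: int):
    return np.triu_indices(m, k=1)


def _problem_rank_matrix(problem: AggregationProblem) -> np.ndarray:
    """(K, M) array: rank of sorted-item j in each input list."""
    index = {item: i for i, item in enumerate(problem.items)}
    return np.stack([_rank_vector(l, index) for l in problem.lists])


def _phi_batch(ranks: np.ndarray, problem: AggregationProblem, list_ranks: np.ndarray) -> np.ndarray:
    """Phi for a batch of candidates given as (S, M) rank matrices."""
    weights = np.asarray(problem.weights)
    if problem.distance == "footrule":
        # (S, K) distances via broadcasting over the K input lists
        d = np.abs(ranks[:, None, :] - list_ranks[None, :, :]).sum(axis=2)
    else:
        iu, iv = _pair_index(ranks.shape[1])
        s_cand = np.sign(ranks[:, iu] - ranks[:, iv])
        s_lists = np.sign(list_ranks[:, iu] - list_ranks[:, iv])
        d = (s_cand[:, None, :] != s_lists[None, :, :]).sum(axis=2)
    return d @ weights


def aggregate_brute_force(
    problem: AggregationProblem, cap: int = BRUTE_FORCE_CAP
) -> AggregationResult:
    """Exact minimizer of Phi by enumerating all M! orderings.

    Ties are broken toward the lexicographically first identifier sequence.
    Raises for M above ``cap``; use a heuristic optimizer
    (:func:`aggregate_cross_entropy` or :func:`aggregate_genetic`) instead.
    """
    m = problem.n_items
    if m > cap:
        raise RankAggregationError(
            f"brute force limited to M <= {cap} items (got {m}); "
            "use aggregate_cross_entropy or aggregate_genetic"
        )
    seqs, ranks = _all_perm_ranks(m)
    phi = _phi_batch(ranks, problem, _problem_rank_matrix(problem))
    k = int(np.argmin(phi))  # first minimum == lexicographically first order
    items = problem.items
    return AggregationResult(
        best_order=tuple(items[i] for i in seqs[k]),
        objective=float(phi[k]),
        method="brute",
    )


def _seed_candidates(problem: AggregationProblem) -> np.ndarray:
    """The input lists themselves, as item-index sequences over sorted items."""
    index = {item: i for i, item in enumerate(problem.items)}
    return np.array([[index[x] for x in l] for l in problem.lists], dtype=np.int64)


def _result_from_seq(seq, phi, problem, method, converged) -> AggregationResult:
    items = problem.items
    return AggregationResult(
        best_order=tuple(items[i] for i in seq),
        objective=float(phi),
        method=method,
        converged=converged,
    )


def aggregate_cross_entropy(
    problem: AggregationProblem,
    *,
    sample_size: int | None = None,
    elite_frac: float = 0.1,
    smoothing: float = 0.7,
    patience: int = 15,
    max_iter: int = 200,
    seed=None,
) -> AggregationResult:
    """Cross-entropy Monte-Carlo minimization of Phi over permutations.

    A position-by-item probability matrix is iteratively re-estimated from the
    elite fraction of sampled orderings and blended with the previous matrix
    (``smoothing`` is the weight on the new estimate).  The search stops after
    ``patience`` iterations without improvement of the best objective, or at
    ``max_iter`` (in which case the result carries ``converged=False``).
    """
    m = problem.n_items
    if m < 2:
        return _result_from_seq([0], 0.0, problem, "cross_entropy", True)
    rng = np.random.default_rng(seed)
    n_samples = sample_size or 50 * m
    n_elite = max(1, int(round(elite_frac * n_samples)))
    list_ranks = _problem_rank_matrix(problem)

    seeds = _seed_candidates(problem)
    seed_phi = _phi_batch(np.argsort(seeds, axis=1), problem, list_ranks)
    best_i = int(np.argmin(seed_phi))
    best_seq, best_phi = seeds[best_i].copy(), float(seed_phi[best_i])

    prob = np.full((m, m), 1.0 / m)
    stagnant = 0
    converged = False
    for _ in range(max_iter):
        samples = np.empty((n_samples, m), dtype=np.int64)
        for s in range(n_samples):
            avail = np.ones(m, dtype=bool)
            for pos in range(m):
                p = prob[pos] * avail
                total = p.sum()
                if total <= 0:
                    p = avail / avail.sum()
                else:
                    p = p / total
                choice = rng.choice(m, p=p)
                samples[s, pos] = choice
                avail[choice] = False
        phi = _phi_batch(np.argsort(samples, axis=1), problem, list_ranks)
        order = np.argsort(phi, kind="stable")
        elite = samples[order[:n_elite]]
        if phi[order[0]] < best_phi:
            best_phi = float(phi[order[0]])
            best_seq = samples[order[0]].copy()
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= patience:
                converged = True
                break
        counts = np.zeros((m, m))
        for pos in range(m):
            counts[pos] = np.bincount(elite[:, pos], minlength=m)
        prob = smoothing * (counts / n_elite) + (1.0 - smoothing) * prob
    return _result_from_seq(best_seq, best_phi, problem, "cross_entropy", converged)


def _order_crossover(p1: np.ndarray, p2: np.ndarray, rng) -> np.ndarray:
    """OX1 order crossover: copy a slice from p1, fill the rest in p2's order."""
    m = len(p1)
    i, j = sorted(rng.choice(m + 1, size=2, replace=False))
    child = np.full(m, -1, dtype=np.int64)
    child[i:j] = p1[i:j]
    used = set(p1[i:j].tolist())
    fill = [x for x in p2 if x not in used]
    k = 0
    for pos in range(m):
        if child[pos] < 0:
            child[pos] = fill[k]
            k += 1
    return child


def aggregate_genetic(
    problem: AggregationProblem,
    *,
    population: int | None = None,
    generations: int = 200,
    mutation_rate: float = 0.1,
    tournament: int = 2,
    patience: int = 30,
    seed=None,
) -> AggregationResult:
    """Genetic-algorithm minimization of Phi over permutations.

    Tournament selection, order crossover, swap mutation, elitism of one.
    Stops early after ``patience`` generations without improvement.
    """
    m = problem.n_items
    if m < 2:
        return _result_from_seq([0], 0.0, problem, "genetic", True)
    rng = np.random.default_rng(seed)
    pop_size = population or 20 * m
    list_ranks = _problem_rank_matrix(problem)

    seeds = _seed_candidates(problem)
    pop = np.vstack(
        [seeds]
        + [rng.permutation(m) for _ in range(max(0, pop_size - len(seeds)))]
    )[:pop_size]
    phi = _phi_batch(np.argsort(pop, axis=1), problem, list_ranks)
    best_i = int(np.argmin(phi))
    best_seq, best_phi = pop[best_i].copy(), float(phi[best_i])

    stagnant = 0
    converged = False
    for _ in range(generations):
        new_pop = [best_seq.copy()]  # elitism
        while len(new_pop) < pop_size:
            idx = rng.integers(len(pop), size=(2, tournament))
            parents = [pop[c[np.argmin(phi[c])]] for c in idx]
            child = _order_crossover(parents[0], parents[1], rng)
            if rng.random() < mutation_rate:
                i, j = rng.choice(m, size=2, replace=False)
                child[i], child[j] = child[j], child[i]
            new_pop.append(child)
        pop = np.array(new_pop)
        phi = _phi_batch(np.argsort(pop, axis=1), problem, list_ranks)
        gen_best = int(np.argmin(phi))
        if phi[gen_best] < best_phi:
            best_phi = float(phi[gen_best])
            best_seq = pop[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= patience:
                converged = True
                break
    return _result_from_seq(best_seq, best_phi, problem, "genetic", converged)


_METHODS = {
    "brute": aggregate_brute_force,
    "cross_entropy": aggregate_cross_entropy,
    "genetic": aggregate_genetic,
}


def aggregate(
    problem: AggregationProblem, method: str = "brute", **kwargs
) -> AggregationResult:
    """Dispatch to the named minimizer ("brute", "cross_entropy", "genetic")."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise RankAggregationError(f"unknown aggregation method {method!r}") from None
    return fn(problem, **kwargs)


def best_algorithm(
    problem: AggregationProblem, method: str = "brute", **kwargs
) -> Hashable:
    """First element of the consensus ordering: the overall winner."""
    return aggregate(problem, method, **kwargs).best_order[0]
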