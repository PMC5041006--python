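"""Genome ranking by aggregation of per-COG partial rankings.

Each COG column of the count matrix induces a *partial ranking* of the
genomes: only genomes with a nonzero count participate, and genome g
precedes genome h when g has strictly fewer copies.  The aggregation task is
to find one total order of all genomes that minimises the summed Kendall tau
disagreement with all of these partial rankings — the Kemeny-optimal
consensus, with rank 1 given to the genome with the fewest paralogs.

Kemeny aggregation is NP-hard, so the working algorithm is a sorting
heuristic ("S-ranking"): starting from a random order, adjacent genomes are
compared over the COGs present in both, and swapped when the lower-ranked
genome wins more columns (has the bigger families more often).  Full passes
repeat until no swap fires or a pass cap is reached; the procedure restarts
from several random orders and reports the mean and standard deviation of
each genome's final rank.  An exhaustive solver over all permutations is
provided as an exact oracle for small instances.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import GeneFamilyMatrix

__all__ = [
    "PartialRanking",
    "RankingResult",
    "partial_rankings_from_matrix",
    "kendall_tau_distance",
    "partial_tau_disagreements",
    "pairwise_win_matrix",
    "kemeny_objective",
    "s_rank",
    "exact_kemeny",
]


@dataclasses.dataclass(frozen=True)
class PartialRanking:
    """The partial ranking a single COG induces on its member genomes."""

    cog_id: str
    member_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for g, v in self.member_counts.items():
            if v < 1:
                raise ValueError(f"COG {self.cog_id!r}: member {g!r} has count {v} < 1")


def partial_rankings_from_matrix(matrix: GeneFamilyMatrix) -> Iterator[PartialRanking]:
    for j, cog in enumerate(matrix.cog_ids):
        col = matrix.counts[:, j]
        members = {
            matrix.genome_ids[i]: int(col[i]) for i in np.flatnonzero(col > 0)
        }
        yield PartialRanking(cog_id=cog, member_counts=members)


# -- Kendall tau machinery -------------------------------------------------

def kendall_tau_distance(order_a: Sequence[str], order_b: Sequence[str]) -> int:
    """Number of element pairs ordered oppositely by two permutations."""
    if set(order_a) != set(order_b) or len(order_a) != len(order_b):
        raise ValueError("orders must be permutations of the same element set")
    pos_b = {x: i for i, x in enumerate(order_b)}
    seq = np.array([pos_b[x] for x in order_a])
    # pairs (i < j) with seq[i] > seq[j] are inversions
    return int(sum((seq[i] > seq[i + 1 :]).sum() for i in range(len(seq) - 1)))


def partial_tau_disagreements(order: Sequence[str], pr: PartialRanking) -> int:
    """Disagreements between a total order and one COG's partial ranking.

    A pair of member genomes with strictly different copy numbers disagrees
    when the genome ranked lower (earlier in ``order``) has the larger
    count; ties and non-members are neutral.
    """
    pos = {g: i for i, g in enumerate(order)}
    members = list(pr.member_counts)
    missing = [g for g in members if g not in pos]
    if missing:
        raise ValueError(f"order does not cover genome {missing[0]!r} of COG {pr.cog_id!r}")
    bad = 0
    for a, b in itertools.combinations(members, 2):
        ca, cb = pr.member_counts[a], pr.member_counts[b]
        if ca == cb:
            continue
        lower_ranked = a if pos[a] < pos[b] else b
        larger_count = a if ca > cb else b
        if lower_ranked == larger_count:
            bad += 1
    return bad


def pairwise_win_matrix(matrix: GeneFamilyMatrix) -> np.ndarray:
    """``W[i, j]`` = number of COGs present in both genomes where i > j.

    This matrix carries everything the objective and the sorting heuristic
    need: the disagreement a total order accrues equals the sum of
    ``W[g, h]`` over genome pairs with g ranked before h.
    """
    counts = matrix.counts
    present = counts > 0
    n = matrix.n_genomes
    w = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = present[i] & present
        w[i] = ((counts[i] > counts) & both).sum(axis=1)
    return w


def kemeny_objective(order: Sequence[str], matrix: GeneFamilyMatrix) -> int:
    """Summed tau disagreement of a total order with all COG partial rankings."""
    if set(order) != set(matrix.genome_ids) or len(order) != matrix.n_genomes:
        raise ValueError("order must be a permutation of the matrix's genomes")
    w = pairwise_win_matrix(matrix)
    idx = [matrix.genome_index(g) for g in order]
    return _objective_from_w(w, idx)


def _objective_from_w(w: np.ndarray, order_idx: Sequence[int]) -> int:
    total = 0
    for pos, a in enumerate(order_idx):
        for b in order_idx[pos + 1 :]:
            total += w[a, b]
    return int(total)


# -- the sorting heuristic -------------------------------------------------

@dataclasses.dataclass
class RankingResult:
    """Outcome of the restarted sorting heuristic.

    ``mean_rank``/``rank_sd`` summarise each genome's final position over
    the restarts (rank 1 = fewest paralogs).  ``consensus_order`` is the
    best order seen: among the restart end states plus the mean-rank
    sorting (ties broken by genome id), the one with the smallest Kemeny
    objective wins, further ties going to the lexicographically smallest
    order.  ``objective`` is that order's exact Kemeny objective.  Picking
    the objective minimiser matters when the pairwise majority relation has
    ties or cycles: individual restarts can stall in locally stable orders,
    and averaging their ranks can blur a cleanly better consensus.
    """

    mean_rank: dict[str, float]
    rank_sd: dict[str, float]
    consensus_order: list[str]
    objective: int
    n_restarts: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genome_id": list(self.mean_rank),
                "mean_rank": list(self.mean_rank.values()),
                "rank_sd": [self.rank_sd[g] for g in self.mean_rank],
            }
        )

    def consensus_rank(self, genome_id: str) -> int:
        return self.consensus_order.index(genome_id) + 1


def _bubble_passes(order: list[int], w: np.ndarray, max_passes: int) -> list[int]:
    """Repeated adjacent-swap passes driven by the pairwise majority vote."""
    n = len(order)
    for _ in range(max_passes):
        swapped = False
        for pos in range(n - 1):
            g1, g2 = order[pos], order[pos + 1]
            # swap when the currently lower-ranked genome wins more shared
            # COGs (has bigger families more often); ties leave order alone
            if w[g1, g2] > w[g2, g1]:
                order[pos], order[pos + 1] = g2, g1
                swapped = True
        if not swapped:
            break
    return order


def s_rank(
    matrix: GeneFamilyMatrix,
    n_restarts: int = 10,
    seed: int = 0,
    max_passes: int | None = None,
) -> RankingResult:
    """Restarted sorting heuristic for the Kemeny consensus.

    Each restart shuffles the genomes with its own sub-seed (derived from
    ``seed`` by a fixed spawning scheme) and sorts by adjacent majority
    comparisons.  Passes are capped at the number of genomes by default:
    the pairwise majority relation may contain cycles, in which case the
    order at the cap stands.  Fully reproducible from the seed.
    """
    if matrix.n_genomes < 1:
        raise ValueError("need at least one genome")
    if n_restarts < 1:
        raise ValueError("n_restarts must be positive")
    n = matrix.n_genomes
    cap = n if max_passes is None else max_passes
    w = pairwise_win_matrix(matrix)
    ranks = np.empty((n_restarts, n), dtype=np.float64)
    restart_orders: list[list[int]] = []
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        order = list(rng.permutation(n))
        order = _bubble_passes(order, w, cap)
        restart_orders.append(order)
        for pos, g in enumerate(order):
            ranks[r, g] = pos + 1
    mean = ranks.mean(axis=0)
    sd = ranks.std(axis=0, ddof=0)
    ids = matrix.genome_ids
    mean_rank_order = sorted(range(n), key=lambda g: (mean[g], ids[g]))
    candidates = [mean_rank_order] + restart_orders
    consensus_idx = min(
        candidates,
        key=lambda o: (_objective_from_w(w, o), tuple(ids[g] for g in o)),
    )
    consensus = [ids[g] for g in consensus_idx]
    objective = _objective_from_w(w, consensus_idx)
    return RankingResult(
        mean_rank={g: float(mean[matrix.genome_index(g)]) for g in ids},
        rank_sd={g: float(sd[matrix.genome_index(g)]) for g in ids},
        consensus_order=consensus,
        objective=objective,
        n_restarts=n_restarts,
        seed=seed,
    )


# -- exact solver (oracle for small instances) -----------------------------

def exact_kemeny(matrix: GeneFamilyMatrix, max_n: int = 9) -> tuple[list[str], int]:
    """Exhaustively minimise the Kemeny objective over all genome orders.

    Factorial cost; refuses more than ``max_n`` genomes.  Ties are broken
    toward the lexicographically smallest optimal order so the result is
    deterministic.
    """
    n = matrix.n_genomes
    if n > max_n:
        raise ValueError(f"exact search over {n}! orders refused (max_n={max_n})")
    w = pairwise_win_matrix(matrix)
    ids = sorted(matrix.genome_ids)
    idx = [matrix.genome_index(g) for g in ids]
    best_order: tuple[int, ...] | None = None
    best_obj = None
    # itertools.permutations over a lexicographically sorted base yields
    # orders in lexicographic sequence, so the first minimum encountered is
    # the lexicographically smallest optimum
    for perm in itertools.permutations(range(n)):
        obj = _objective_from_w(w, [idx[k] for k in perm])
        if best_obj is None or obj < best_obj:
            best_obj = obj
            best_order = perm
    assert best_order is not None and best_obj is not None
    return [ids[k] for k in best_order], int(best_obj)
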