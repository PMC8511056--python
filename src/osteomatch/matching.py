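"""Shape-based ranking of candidate femora for each query acetabulum.

For a query acetabulum, the raw coordinates of the query and of every
candidate femur are jointly superimposed (GPA, scaled by default) and each
femur is scored by the Manhattan distance — the sum of absolute coordinate
differences — between its flattened Procrustes coordinates and the
query's.  The femur with the smallest distance is the "first indication";
candidates are reported in ascending distance order.  The procedure is
repeated independently for every acetabulum in an assemblage.

Also provided: rank evaluation against ground truth (rank histogram,
first-indication and within-top-k rates, mean accuracy error in
individuals) and, as an extension beyond per-query ranking, a global
one-to-one assignment minimizing the total Manhattan distance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ComputationError
from .landmarks import Assemblage, BoneType, LandmarkConfiguration
from .superimposition import generalized_procrustes

logger = logging.getLogger(__name__)

__all__ = [
    "manhattan_distance",
    "MatchRanking",
    "rank_candidates",
    "rank_all",
    "SortingReport",
    "evaluate_rankings",
    "GlobalAssignment",
    "minimum_cost_assignment",
    "global_assignment",
]


def manhattan_distance(x, y) -> float:
    """Sum of absolute coordinate differences between two flat vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ComputationError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    return float(np.abs(x - y).sum())


@dataclass(frozen=True)
class MatchRanking:
    """Candidates for one query acetabulum, ascending by Manhattan distance."""

    query_id: str
    candidates: tuple[tuple[str, float], ...]
    scaled: bool

    def __post_init__(self):
        d = [dist for _, dist in self.candidates]
        if any(b < a for a, b in zip(d, d[1:])):
            raise ValueError("candidate distances must be non-decreasing")

    @property
    def candidate_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.candidates)

    def rank_of(self, specimen_id: str) -> int | None:
        """1-based rank of a candidate, or None if absent."""
        for rank, (cid, _) in enumerate(self.candidates, start=1):
            if cid == specimen_id:
                return rank
        return None

    def top(self, k: int) -> tuple[tuple[str, float], ...]:
        return self.candidates[:k]


def _check_sides(cfgs: Sequence[LandmarkConfiguration]) -> None:
    sides = {c.side for c in cfgs}
    if len(sides) > 1:
        raise ComputationError(
            "mixed sides in comparison set; mirror left specimens to the "
            "right-side convention first (Assemblage.normalized_to_right)"
        )


def _sorted_candidates(
    ids: Sequence[str], dists: Sequence[float]
) -> tuple[tuple[str, float], ...]:
    order = sorted(range(len(ids)), key=lambda i: (dists[i], ids[i]))
    for a, b in zip(order, order[1:]):
        if dists[a] == dists[b]:
            logger.info("distance tie between %s and %s broken lexicographically", ids[a], ids[b])
    return tuple((ids[i], float(dists[i])) for i in order)


def rank_candidates(
    query: LandmarkConfiguration,
    femora: Sequence[LandmarkConfiguration],
    *,
    scale: bool = True,
) -> MatchRanking:
    """Rank candidate femora for one acetabulum by Manhattan shape distance.

    The query and all candidates are superimposed jointly; distances are
    computed in the resulting Procrustes coordinate space.  Ties are broken
    by lexicographic specimen id (and logged).
    """
    if len(femora) == 0:
        raise ComputationError("rank_candidates requires at least one candidate femur")
    if query.bone_type is not BoneType.ACETABULUM:
        raise ComputationError(f"query {query.specimen_id!r} is not an acetabulum")
    for f in femora:
        if f.bone_type is not BoneType.FEMUR:
            raise ComputationError(f"candidate {f.specimen_id!r} is not a femur")
    _check_sides([query, *femora])
    aligned = generalized_procrustes([query, *femora], scale=scale)
    q = aligned.flat(0)
    dists = [manhattan_distance(q, aligned.flat(i)) for i in range(1, len(aligned))]
    ids = [f.specimen_id for f in femora]
    return MatchRanking(query.specimen_id, _sorted_candidates(ids, dists), scaled=scale)


def rank_all(
    assemblage: Assemblage,
    *,
    scale: bool = True,
    shared_gpa: bool = False,
) -> list[MatchRanking]:
    """Rank candidates for every acetabulum in an assemblage.

    By default each query gets its own joint superimposition with all
    femora.  ``shared_gpa=True`` instead performs a single GPA of every
    specimen and reads all distances from that one coordinate system — an
    approximation that trades fidelity for speed.
    """
    acetabula, femora = assemblage.acetabula, assemblage.femora
    if not acetabula:
        raise ComputationError("assemblage contains no acetabula")
    if not femora:
        raise ComputationError("assemblage contains no femora")
    if not shared_gpa:
        return [rank_candidates(q, femora, scale=scale) for q in acetabula]

    _check_sides(acetabula + femora)
    aligned = generalized_procrustes(acetabula + femora, scale=scale)
    fem_ids = [f.specimen_id for f in femora]
    n_a = len(acetabula)
    rankings = []
    for qi, q in enumerate(acetabula):
        qv = aligned.flat(qi)
        dists = [manhattan_distance(qv, aligned.flat(n_a + j)) for j in range(len(femora))]
        rankings.append(MatchRanking(q.specimen_id, _sorted_candidates(fem_ids, dists), scale))
    return rankings


@dataclass(frozen=True)
class SortingReport:
    """Rank-based accuracy summary of a set of rankings against ground truth.

    ``mean_rank_error`` is the accuracy error in individuals: the mean of
    (rank of the true match − 1), i.e. how many false candidates were
    ranked above the true femur, with its standard deviation.  Queries
    whose true femur is absent from the candidate list are counted as
    ``n_unmatchable`` and excluded from the rates.
    """

    n_queries: int
    rank_histogram: dict[int, int]
    first_indication_rate: float  # % of queries with the true match ranked 1
    within_top_k_rate: dict[int, float]  # k -> %
    mean_rank_error: float
    sd_rank_error: float
    per_query_ranks: dict[str, int]
    n_unmatchable: int = 0
    unmatchable_ids: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "n_queries": self.n_queries,
            "rank_histogram": {str(k): v for k, v in sorted(self.rank_histogram.items())},
            "first_indication_rate": self.first_indication_rate,
            "within_top_k_rate": {str(k): v for k, v in sorted(self.within_top_k_rate.items())},
            "mean_rank_error": self.mean_rank_error,
            "sd_rank_error": self.sd_rank_error,
            "per_query_ranks": dict(sorted(self.per_query_ranks.items())),
            "n_unmatchable": self.n_unmatchable,
            "unmatchable_ids": list(self.unmatchable_ids),
        }


def evaluate_rankings(
    rankings: Iterable[MatchRanking],
    truth: Mapping[str, str],
) -> SortingReport:
    """Score rankings against true acetabulum→femur pairings.

    ``truth`` maps each query (acetabulum) specimen id to its true femur
    specimen id; see :meth:`Assemblage.true_pairs`.  Queries without a
    truth entry, or whose true femur is not among the candidates, are
    flagged unmatchable and excluded from the rates.
    """
    ranks: dict[str, int] = {}
    unmatchable: list[str] = []
    for r in rankings:
        true_fem = truth.get(r.query_id)
        rank = r.rank_of(true_fem) if true_fem is not None else None
        if rank is None:
            unmatchable.append(r.query_id)
        else:
            ranks[r.query_id] = rank
    n = len(ranks)
    histogram: dict[int, int] = {}
    for rank in ranks.values():
        histogram[rank] = histogram.get(rank, 0) + 1
    if n:
        arr = np.array(list(ranks.values()))
        max_rank = int(arr.max())
        within = {
            k: 100.0 * float((arr <= k).sum()) / n for k in range(1, max_rank + 1)
        }
        errors = arr - 1
        mean_err = float(errors.mean())
        sd_err = float(errors.std(ddof=1)) if n > 1 else 0.0
        first = within[1]
    else:
        within, mean_err, sd_err, first = {}, float("nan"), float("nan"), float("nan")
    return SortingReport(
        n_queries=n,
        rank_histogram=histogram,
        first_indication_rate=first,
        within_top_k_rate=within,
        mean_rank_error=mean_err,
        sd_rank_error=sd_err,
        per_query_ranks=ranks,
        n_unmatchable=len(unmatchable),
        unmatchable_ids=tuple(sorted(unmatchable)),
    )


@dataclass(frozen=True)
class GlobalAssignment:
    """Minimum-total-cost one-to-one matching (extension beyond per-query ranking)."""

    pairs: dict[str, str]  # acetabulum id -> femur id
    total_cost: float
    unassigned_acetabula: tuple[str, ...]
    unassigned_femora: tuple[str, ...]
    note: str = "extension"


def minimum_cost_assignment(cost: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Minimum-cost bipartite assignment of a (possibly rectangular) cost matrix."""
    cost = np.asarray(cost, dtype=float)
    rows, cols = linear_sum_assignment(cost)
    return rows, cols, float(cost[rows, cols].sum())


def global_assignment(
    acetabula: Sequence[LandmarkConfiguration],
    femora: Sequence[LandmarkConfiguration],
    *,
    scale: bool = True,
) -> GlobalAssignment:
    """Jointly assign acetabula to femora minimizing total Manhattan distance.

    All specimens share a single GPA; with unequal counts the excess
    elements are left unassigned.  This goes beyond independent per-query
    ranking and is flagged as an extension in the result.
    """
    if not acetabula or not femora:
        raise ComputationError("global_assignment requires both acetabula and femora")
    _check_sides(list(acetabula) + list(femora))
    aligned = generalized_procrustes(list(acetabula) + list(femora), scale=scale)
    n_a = len(acetabula)
    cost = np.array(
        [
            [manhattan_distance(aligned.flat(i), aligned.flat(n_a + j)) for j in range(len(femora))]
            for i in range(n_a)
        ]
    )
    rows, cols, total = minimum_cost_assignment(cost)
    pairs = {acetabula[i].specimen_id: femora[j].specimen_id for i, j in zip(rows, cols)}
    un_a = tuple(a.specimen_id for i, a in enumerate(acetabula) if i not in set(rows))
    un_f = tuple(f.specimen_id for j, f in enumerate(femora) if j not in set(cols))
    return GlobalAssignment(pairs, total, un_a, un_f)
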