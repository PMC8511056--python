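"""Osteometric compatibility filter for the top shape candidates.

Shape ranking is combined with a published linear relation between the
maximum femoral head diameter (FHD) and the maximum diameter of the
acetabulum (ODA), both in mm:

    ODA = 4.725 + 1.027 * FHD  (± 2.54 acceptance half-width)

For each query acetabulum the top-k shape candidates (k = 2 by default)
are examined in rank order; a candidate is metrically compatible when the
acetabulum's observed ODA falls inside the closed interval predicted from
the candidate femur's FHD.  The first compatible candidate is assigned;
if every top-k candidate is rejected the query is left unassigned — the
filter can veto the shape method's indication, trading a possible miss for
protection against confident wrong matches.  Missing measurements degrade
gracefully: compatibility becomes "unknown", which is treated as
compatible with a logged warning, so a partially measured assemblage still
sorts on shape alone.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ComputationError
from .landmarks import HipMeasurements
from .matching import MatchRanking

logger = logging.getLogger(__name__)

__all__ = [
    "FilterParams",
    "DEFAULT_FILTER",
    "Compatibility",
    "predict_oda_interval",
    "metric_compatibility",
    "is_metric_compatible",
    "AssignmentResult",
    "combined_sort",
]


@dataclass(frozen=True)
class FilterParams:
    """FHD→ODA regression constants and the symmetric acceptance half-width (mm)."""

    intercept: float = 4.725
    slope: float = 1.027
    tolerance: float = 2.54

    def __post_init__(self):
        if not self.tolerance > 0:
            raise ValueError(f"tolerance must be positive, got {self.tolerance}")


DEFAULT_FILTER = FilterParams()


class Compatibility(str, enum.Enum):
    COMPATIBLE = "compatible"
    INCOMPATIBLE = "incompatible"
    UNKNOWN = "unknown"


def predict_oda_interval(
    fhd: float, params: FilterParams = DEFAULT_FILTER
) -> tuple[float, float]:
    """Closed acceptance interval [lo, hi] for ODA (mm) given FHD (mm)."""
    if not fhd > 0:
        raise ComputationError(f"fhd must be positive, got {fhd}")
    mid = params.intercept + params.slope * fhd
    return (mid - params.tolerance, mid + params.tolerance)


def metric_compatibility(
    m: HipMeasurements, params: FilterParams = DEFAULT_FILTER
) -> Compatibility:
    """Tri-state metric compatibility of a femur/acetabulum measurement pair."""
    if m.fhd is None or m.oda is None:
        return Compatibility.UNKNOWN
    lo, hi = predict_oda_interval(m.fhd, params)
    ok = lo <= m.oda <= hi
    return Compatibility.COMPATIBLE if ok else Compatibility.INCOMPATIBLE


def is_metric_compatible(
    m: HipMeasurements, params: FilterParams = DEFAULT_FILTER
) -> bool:
    """Boolean view of :func:`metric_compatibility`; unknown passes with a warning."""
    c = metric_compatibility(m, params)
    if c is Compatibility.UNKNOWN:
        logger.warning(
            "missing FHD or ODA measurement; treating pair as metrically compatible"
        )
        return True
    return c is Compatibility.COMPATIBLE


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of combined shape + metric sorting for one query acetabulum."""

    query_id: str
    status: str  # "matched" | "unassigned"
    matched_id: str | None = None
    shape_rank_of_match: int | None = None
    rejected: tuple[tuple[str, str], ...] = ()  # (candidate_id, reason)


def combined_sort(
    rankings: Iterable[MatchRanking],
    measurements: Mapping[str, HipMeasurements],
    *,
    top_k: int = 2,
    params: FilterParams = DEFAULT_FILTER,
) -> list[AssignmentResult]:
    """Assign each query to its first metrically compatible top-k shape candidate.

    Candidates are examined strictly in shape-rank order; the first whose
    FHD-predicted ODA interval contains the query's ODA wins.  If all
    ``top_k`` candidates are metrically rejected the query is reported
    unassigned, with the rejection reasons (including the interval bounds)
    recorded per candidate.
    """
    if top_k < 1:
        raise ComputationError(f"top_k must be >= 1, got {top_k}")
    results: list[AssignmentResult] = []
    for ranking in rankings:
        q_meas = measurements.get(ranking.query_id)
        oda = q_meas.oda if q_meas is not None else None
        rejected: list[tuple[str, str]] = []
        outcome: AssignmentResult | None = None
        for rank, (cand_id, _) in enumerate(ranking.top(top_k), start=1):
            c_meas = measurements.get(cand_id)
            fhd = c_meas.fhd if c_meas is not None else None
            pair = HipMeasurements(fhd=fhd, oda=oda)
            if is_metric_compatible(pair, params):
                outcome = AssignmentResult(
                    query_id=ranking.query_id,
                    status="matched",
                    matched_id=cand_id,
                    shape_rank_of_match=rank,
                    rejected=tuple(rejected),
                )
                break
            lo, hi = predict_oda_interval(fhd, params)
            rejected.append(
                (
                    cand_id,
                    f"oda {oda:.3f} outside predicted interval "
                    f"[{lo:.3f}, {hi:.3f}] for fhd {fhd:.3f}",
                )
            )
            logger.info(
                "metric rejection: query %s candidate %s (%s)",
                ranking.query_id,
                cand_id,
                rejected[-1][1],
            )
        if outcome is None:
            outcome = AssignmentResult(
                query_id=ranking.query_id, status="unassigned", rejected=tuple(rejected)
            )
        results.append(outcome)
    return results
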