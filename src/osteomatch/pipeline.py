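"""End-to-end orchestration: sort, evaluate, blind-test, repeatability runs.

Thin, file-oriented layer over the library modules.  Every run is
deterministic for fixed inputs and configuration; CSV and JSON outputs are
written with fixed float formatting so reruns are byte-identical.
Distances are printed to 9 significant digits; rates to 1 decimal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, InputFormatError
from .landmarks import Assemblage, HipMeasurements, read_landmark_table
from .matching import MatchRanking, SortingReport, evaluate_rankings, rank_all
from .metric_filter import DEFAULT_FILTER, AssignmentResult, FilterParams, combined_sort
from .repeatability import RepeatSet, percentage_error

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_sort",
    "run_evaluate",
    "run_blind_test",
    "run_repeatability",
    "write_rankings_csv",
    "read_rankings_csv",
    "write_assignments_csv",
]


@dataclass
class RunConfig:
    """Configuration of a sorting run."""

    scale: bool = True
    shared_gpa: bool = False
    top_k: int = 2
    metric_filter: bool = False
    normalize_sides: bool = True
    filter_params: FilterParams = field(default_factory=lambda: DEFAULT_FILTER)


def write_rankings_csv(rankings: Iterable[MatchRanking], path: str | Path) -> None:
    rows = [
        {
            "query_id": r.query_id,
            "rank": rank,
            "candidate_id": cid,
            "manhattan_distance": f"{dist:.9g}",
        }
        for r in rankings
        for rank, (cid, dist) in enumerate(r.candidates, start=1)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def read_rankings_csv(path: str | Path) -> list[MatchRanking]:
    df = pd.read_csv(path)
    needed = {"query_id", "rank", "candidate_id", "manhattan_distance"}
    if not needed <= set(df.columns):
        raise InputFormatError(f"rankings CSV missing columns: {sorted(needed - set(df.columns))}")
    rankings = []
    for qid, grp in df.groupby("query_id", sort=False):
        grp = grp.sort_values("rank")
        cands = tuple(
            (str(row.candidate_id), float(row.manhattan_distance)) for row in grp.itertuples()
        )
        rankings.append(MatchRanking(str(qid), cands, scaled=True))
    return rankings


def write_assignments_csv(results: Sequence[AssignmentResult], path: str | Path) -> None:
    rows = [
        {
            "query_id": r.query_id,
            "status": r.status,
            "matched_id": r.matched_id or "",
            "shape_rank_of_match": "" if r.shape_rank_of_match is None else r.shape_rank_of_match,
            "rejected": "; ".join(f"{cid}: {reason}" for cid, reason in r.rejected),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def run_sort(
    assemblage: Assemblage | str | Path,
    config: RunConfig | None = None,
    *,
    rankings_out: str | Path | None = None,
    assignments_out: str | Path | None = None,
) -> tuple[list[MatchRanking], list[AssignmentResult] | None]:
    """Rank every acetabulum's candidates; optionally apply the metric filter."""
    config = config or RunConfig()
    if not isinstance(assemblage, Assemblage):
        assemblage = read_landmark_table(assemblage)
    if config.normalize_sides:
        assemblage = assemblage.normalized_to_right()
    rankings = rank_all(assemblage, scale=config.scale, shared_gpa=config.shared_gpa)
    for r in rankings:
        if not all(np.isfinite(d) for _, d in r.candidates):
            raise ComputationError(f"non-finite distance in ranking for {r.query_id}")
    assignments = None
    if config.metric_filter:
        assignments = combined_sort(
            rankings,
            assemblage.measurements,
            top_k=config.top_k,
            params=config.filter_params,
        )
    if rankings_out is not None:
        write_rankings_csv(rankings, rankings_out)
    if assignments is not None and assignments_out is not None:
        write_assignments_csv(assignments, assignments_out)
    return rankings, assignments


def run_evaluate(
    rankings: Sequence[MatchRanking] | str | Path,
    truth_source: Assemblage | Mapping[str, str] | str | Path,
    *,
    report_out: str | Path | None = None,
) -> SortingReport:
    """Score rankings against ground truth and optionally write a JSON report."""
    if not isinstance(rankings, (list, tuple)):
        rankings = read_rankings_csv(rankings)
    if isinstance(truth_source, (str, Path)):
        truth_source = read_landmark_table(truth_source)
    truth = (
        truth_source.true_pairs() if isinstance(truth_source, Assemblage) else dict(truth_source)
    )
    report = evaluate_rankings(rankings, truth)
    if report_out is not None:
        Path(report_out).write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    return report


def run_blind_test(
    assemblages: Sequence[Assemblage | str | Path],
    config: RunConfig | None = None,
    *,
    report_out: str | Path | None = None,
) -> dict:
    """Per-assemblage correct counts, shape-only and shape+metrics.

    For each artificially commingled assemblage with known truth, counts
    how many queries the first shape indication reassociates correctly
    ("gm_only") and how many the combined shape+metric procedure does
    ("gm_metrics", unassigned counting as an error), then summarises the
    error counts as mean ± SD across assemblages.
    """
    config = config or RunConfig()
    per: list[dict] = []
    for item in assemblages:
        assemblage = item if isinstance(item, Assemblage) else read_landmark_table(item)
        if not assemblage.truth:
            raise InputFormatError("blind test requires ground truth (individual_id column)")
        truth = assemblage.true_pairs()
        norm = assemblage.normalized_to_right() if config.normalize_sides else assemblage
        rankings = rank_all(norm, scale=config.scale, shared_gpa=config.shared_gpa)
        n = len(truth)
        gm_correct = sum(
            1 for r in rankings if truth.get(r.query_id) == r.candidates[0][0]
        )
        assignments = combined_sort(
            rankings, assemblage.measurements, top_k=config.top_k, params=config.filter_params
        )
        gm_metric_correct = sum(
            1 for a in assignments if a.status == "matched" and truth.get(a.query_id) == a.matched_id
        )
        per.append(
            {
                "n": n,
                "gm_only_correct": gm_correct,
                "gm_metrics_correct": gm_metric_correct,
                "gm_only": f"{gm_correct}/{n}",
                "gm_metrics": f"{gm_metric_correct}/{n}",
            }
        )
    gm_errors = np.array([p["n"] - p["gm_only_correct"] for p in per], dtype=float)
    gmm_errors = np.array([p["n"] - p["gm_metrics_correct"] for p in per], dtype=float)
    report = {
        "assemblages": per,
        "gm_only_mean_error": float(gm_errors.mean()),
        "gm_only_sd_error": float(gm_errors.std(ddof=1)) if len(per) > 1 else 0.0,
        "gm_metrics_mean_error": float(gmm_errors.mean()),
        "gm_metrics_sd_error": float(gmm_errors.std(ddof=1)) if len(per) > 1 else 0.0,
    }
    if report_out is not None:
        Path(report_out).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def run_repeatability(
    repeats_table: str | Path | pd.DataFrame,
    *,
    superimpose: bool = True,
    report_out: str | Path | None = None,
) -> dict:
    """Digitization-error report from a repeats CSV.

    The table is a landmark table with additional ``repeat_id`` and
    ``observer_id`` columns; repeats are grouped per (specimen, observer).
    """
    df = repeats_table if isinstance(repeats_table, pd.DataFrame) else pd.read_csv(repeats_table)
    for col in ("repeat_id", "observer_id"):
        if col not in df.columns:
            raise InputFormatError(f"repeats table missing column {col!r}")
    report: dict = {}
    for (spec, obs), grp in df.groupby(["specimen_id", "observer_id"], sort=True):
        repeats = []
        for _, rep_grp in grp.groupby("repeat_id", sort=True):
            sub = rep_grp.drop(columns=["repeat_id", "observer_id"])
            sub = sub.assign(specimen_id=str(spec))
            repeats.append(_config_from_rows(sub))
        rs = RepeatSet(str(spec), str(obs), tuple(repeats))
        report[f"{spec}/{obs}"] = percentage_error(rs, superimpose=superimpose).to_dict()
    if report_out is not None:
        Path(report_out).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _config_from_rows(rows: pd.DataFrame):
    from .landmarks import BoneType, LandmarkConfiguration, N_LANDMARKS, Side

    rows = rows.sort_values("landmark")
    idx = sorted(rows["landmark"].astype(int))
    if idx != list(range(1, N_LANDMARKS + 1)):
        raise InputFormatError(f"repeat block has landmark indices {idx}")
    return LandmarkConfiguration(
        specimen_id=str(rows["specimen_id"].iloc[0]),
        bone_type=BoneType(str(rows["bone_type"].iloc[0])),
        side=Side(str(rows["side"].iloc[0])),
        coords=rows[["x", "y", "z"]].to_numpy(dtype=float),
    )
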