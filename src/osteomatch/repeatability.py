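"""Intra-/inter-observer landmark digitization error.

Repeated digitizations of the same specimen quantify placement precision:
for each landmark, the mean Euclidean deviation (mm) of each repeat's
point from the across-repeat mean point, and a scale-free percentage
error obtained by normalizing the deviation by the mean centroid size of
the repeats.  The specimen-level figure is the average percentage error
across the 11 landmarks.

Repeats recorded in different digitizer sessions live in unrelated
coordinate frames, so by default they are rigidly superimposed (GPA
without scaling, preserving the mm scale) before deviations are computed.
Set ``superimpose=False`` for repeats already expressed in a common frame,
in which case the per-landmark deviation is the direct formula with no
alignment step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError
from .landmarks import LandmarkConfiguration
from .superimposition import centroid_size, generalized_procrustes

__all__ = ["RepeatSet", "ErrorReport", "landmark_deviations", "percentage_error"]


@dataclass(frozen=True)
class RepeatSet:
    """Repeated digitizations of one specimen by one observer."""

    specimen_id: str
    observer_id: str
    repeats: tuple[LandmarkConfiguration, ...]

    def __post_init__(self):
        object.__setattr__(self, "repeats", tuple(self.repeats))
        if len(self.repeats) < 2:
            raise ComputationError("a repeat set requires at least 2 digitizations")
        first = self.repeats[0]
        for r in self.repeats[1:]:
            if (
                r.bone_type != first.bone_type
                or r.side != first.side
                or r.n_landmarks != first.n_landmarks
            ):
                raise ComputationError(
                    "repeats must share bone type, side and landmark count"
                )


@dataclass(frozen=True)
class ErrorReport:
    per_landmark_deviation_mm: np.ndarray
    per_landmark_percent: np.ndarray
    specimen_average_percent: float
    percent_range: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "per_landmark_deviation_mm": [float(v) for v in self.per_landmark_deviation_mm],
            "per_landmark_percent": [float(v) for v in self.per_landmark_percent],
            "specimen_average_percent": float(self.specimen_average_percent),
            "percent_range": [float(v) for v in self.percent_range],
        }


def _repeat_coords(rs: RepeatSet, superimpose: bool) -> np.ndarray:
    if superimpose:
        # rigid only: centroid sizes (mm) are preserved exactly
        aligned = generalized_procrustes(rs.repeats, scale=False)
        return aligned.shapes
    return np.stack([r.coords for r in rs.repeats])


def landmark_deviations(rs: RepeatSet, *, superimpose: bool = True) -> np.ndarray:
    """Per-landmark mean Euclidean deviation (mm) from the across-repeat mean."""
    coords = _repeat_coords(rs, superimpose)
    mean_cfg = coords.mean(axis=0)
    return np.linalg.norm(coords - mean_cfg, axis=2).mean(axis=0)


def percentage_error(rs: RepeatSet, *, superimpose: bool = True) -> ErrorReport:
    """Per-landmark and specimen-average percentage digitization error.

    Per-landmark % = 100 × mean deviation / mean centroid size of the
    repeats; the centroid-size normalizer makes the figure invariant to
    rigid motion of any repeat and inversely proportional to uniform
    specimen size when deviations are held fixed in mm.
    """
    devs = landmark_deviations(rs, superimpose=superimpose)
    mean_cs = float(np.mean([centroid_size(r) for r in rs.repeats]))
    percents = 100.0 * devs / mean_cs
    return ErrorReport(
        per_landmark_deviation_mm=devs,
        per_landmark_percent=percents,
        specimen_average_percent=float(percents.mean()),
        percent_range=(float(percents.min()), float(percents.max())),
    )
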