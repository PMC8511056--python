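"""Procrustes superimposition of landmark configurations.

Shape comparison requires removing the nuisance parameters of the digitizer
frame — position, orientation and (optionally) size.  This module provides
centroid size, ordinary Procrustes alignment of one configuration onto
another, and iterative generalized Procrustes analysis (GPA) of a whole
set: every configuration is centred, optionally scaled to unit centroid
size, and rotated to a running consensus until the consensus stabilises.
The converged set is finally rotated as a whole so the consensus lies on
its principal axes with a deterministic sign convention, making the output
orientation reproducible; rigid-motion-invariant distances are unaffected
by this global rotation.

Scaling removes size: two specimens of near-identical size but different
articular shape sit close together in the unscaled coordinate space, which
is exactly the confound that motivates comparing Procrustes *shape*
coordinates.  The unscaled variant remains available (``scale=False``) and
retains original centroid sizes exactly.

Rotations are restricted to proper rotations (determinant +1): reflections
are never introduced silently, side mirroring is an explicit upstream step.
Rim semilandmarks are treated as fixed landmarks — the digitization
protocol places midpoints manually and no sliding step is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ComputationError
from .landmarks import LandmarkConfiguration

__all__ = [
    "centroid_size",
    "align_pair",
    "AlignResult",
    "generalized_procrustes",
    "AlignedSet",
]

_DEGENERATE_TOL = 1e-12


def _as_coords(cfg) -> np.ndarray:
    if isinstance(cfg, LandmarkConfiguration):
        return cfg.coords
    arr = np.asarray(cfg, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ComputationError(f"expected (n, 3) coordinates, got shape {arr.shape}")
    return arr


def centroid_size(cfg) -> float:
    """Square root of summed squared landmark distances from the centroid (mm)."""
    coords = _as_coords(cfg)
    if coords.shape[0] < 2:
        raise ComputationError("centroid size requires at least 2 landmarks")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs < _DEGENERATE_TOL:
        raise ComputationError("degenerate configuration: all landmarks coincident")
    return cs


def _optimal_rotation(target: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||target - source @ R||_F (both centred)."""
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


@dataclass(frozen=True)
class AlignResult:
    """Ordinary Procrustes fit of configuration B onto configuration A."""

    aligned: np.ndarray  # B translated/scaled/rotated into A's frame
    rotation: np.ndarray  # 3x3 proper rotation applied to centred B
    scale: float  # scale factor applied to B (1.0 when scale=False)
    residual: float  # root-sum-of-squares distance to A, in A's frame


def align_pair(a, b, *, scale: bool = True) -> AlignResult:
    """Superimpose configuration ``b`` onto ``a`` (ordinary Procrustes).

    ``b`` is translated to ``a``'s centroid, scaled to ``a``'s centroid size
    when ``scale`` is true, and rotated (proper rotation only) to minimize
    the root-sum-of-squares distance to ``a``.  The residual is reported in
    ``a``'s frame; divide by ``centroid_size(a)`` for the unit-size shape
    residual.
    """
    A, B = _as_coords(a), _as_coords(b)
    if A.shape != B.shape:
        raise ComputationError(f"landmark count mismatch: {A.shape[0]} vs {B.shape[0]}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    s = centroid_size(A) / centroid_size(B) if scale else 1.0
    r = _optimal_rotation(Ac, s * Bc)
    fitted = s * Bc @ r
    residual = float(np.linalg.norm(Ac - fitted))
    return AlignResult(aligned=fitted + ca, rotation=r, scale=s, residual=residual)


@dataclass(frozen=True)
class AlignedSet:
    """Result of a generalized Procrustes superimposition.

    ``shapes`` is an (n, k, 3) array of Procrustes coordinates in input
    order; ``centroid_sizes`` holds the original sizes (mm); ``consensus``
    is the arithmetic mean of the aligned shapes.
    """

    shapes: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    scaled: bool
    iterations: int
    converged: bool
    specimen_ids: tuple[str, ...] | None = None

    def __len__(self) -> int:
        return self.shapes.shape[0]

    def flat(self, i: int) -> np.ndarray:
        """Flattened (3k,) Procrustes coordinates of shape ``i``."""
        return self.shapes[i].ravel()


def generalized_procrustes(
    cfgs: Sequence,
    *,
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedSet:
    """Iterative GPA of one or more configurations.

    All configurations are centred (and scaled to unit centroid size when
    ``scale``), then iteratively rotated to the running consensus until the
    consensus changes by less than ``tol`` (root-sum-of-squares) or
    ``max_iter`` is reached; non-convergence is reported via the
    ``converged`` flag, not raised.  Finally the whole set is rotated so
    the consensus is aligned with its principal axes (first two axis signs
    fixed by largest-magnitude loading, third axis their cross product, so
    the rotation stays proper).
    """
    if len(cfgs) == 0:
        raise ComputationError("generalized_procrustes requires at least 1 configuration")
    ids = tuple(c.specimen_id for c in cfgs) if all(
        isinstance(c, LandmarkConfiguration) for c in cfgs
    ) else None
    coords = [_as_coords(c) for c in cfgs]
    k = coords[0].shape[0]
    if any(c.shape[0] != k for c in coords):
        counts = sorted({c.shape[0] for c in coords})
        raise ComputationError(f"mixed landmark counts: {counts}")
    sizes = np.array([centroid_size(c) for c in coords])
    shapes = np.stack([c - c.mean(axis=0) for c in coords])
    if scale:
        shapes = shapes / sizes[:, None, None]

    consensus = shapes[0].copy()
    iterations, converged = 0, True
    if len(shapes) > 1:
        converged = False
        for iterations in range(1, max_iter + 1):
            for i in range(len(shapes)):
                shapes[i] = shapes[i] @ _optimal_rotation(consensus, shapes[i])
            new_consensus = shapes.mean(axis=0)
            change = float(np.linalg.norm(new_consensus - consensus))
            consensus = new_consensus
            if change < tol:
                converged = True
                break

    # deterministic principal-axis orientation of the whole aligned set
    _, vecs = np.linalg.eigh(consensus.T @ consensus)
    axes = vecs[:, ::-1]  # descending variance
    for j in range(2):
        if axes[np.argmax(np.abs(axes[:, j])), j] < 0:
            axes[:, j] *= -1.0
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    shapes = shapes @ axes
    consensus = shapes.mean(axis=0)

    return AlignedSet(
        shapes=shapes,
        centroid_sizes=sizes,
        consensus=consensus,
        scaled=scale,
        iterations=iterations,
        converged=converged,
        specimen_ids=ids,
    )
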