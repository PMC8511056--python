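"""Synthetic paired acetabulum/femur landmark data with ground truth.

The generator emulates the statistical structure the matching method
relies on: the two articular surfaces of one hip interlock, so their
landmark configurations are (near-)coincident in articulated pose and
share the individual's shape; different individuals differ in shape and
size; each digitization adds independent placement noise; and every bone
is recorded in its own arbitrary digitizer frame.

Construction per individual:

1. start from a canonical 11-landmark template (rim points on a 27 mm
   circle, fossa/fovea points on a 10 mm inner circle sunk 15 mm along
   the pole axis);
2. apply a smooth low-dimensional shape deformation — anisotropic axis
   scaling, rim ellipticity, fossa offset — with coefficients drawn
   Normal(0, shape_sd), identically to both bones (matching surfaces
   interlock, so they share shape);
3. draw FHD ~ Normal(44.89, 3.83) mm and scale both configurations
   proportionally;
4. add independent per-coordinate Gaussian digitization noise to each
   bone and move each by an independent random rigid motion;
5. set ODA = 4.725 + 1.027·FHD + Normal(0, oda_residual_sd).

All randomness flows through one ``numpy.random.Generator`` (PCG64 via
``default_rng``), so identical parameters and seed reproduce the
assemblage bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ComputationError
from .metric_filter import DEFAULT_FILTER
from .landmarks import (
    Assemblage,
    BoneType,
    HipMeasurements,
    LandmarkConfiguration,
    Side,
    mirror_configuration,
)

__all__ = [
    "RIM_RADIUS_MM",
    "FOSSA_RADIUS_MM",
    "FOSSA_DEPTH_MM",
    "TEMPLATE_FHD_MM",
    "SimulationParams",
    "GroundTruth",
    "template_pair",
    "generate_individual",
    "generate_assemblage",
]

# canonical template geometry (anatomically plausible scale, mm)
RIM_RADIUS_MM = 27.0
FOSSA_RADIUS_MM = 10.0
FOSSA_DEPTH_MM = 15.0
TEMPLATE_FHD_MM = 2.0 * RIM_RADIUS_MM

# rim angles (degrees) in scheme order 1..8: four fixed points at the
# superior / notch / anterior / posterior positions, then the arc
# midpoints 1-4, 2-4, 2-3, 1-3
_RIM_ANGLES_DEG = {1: 90.0, 2: 270.0, 3: 0.0, 4: 180.0, 5: 135.0, 6: 225.0, 7: 315.0, 8: 45.0}
_FOSSA_ANGLES_DEG = {9: 90.0, 10: 180.0, 11: 0.0}

# fixed rigid transform separating the femur template from the acetabulum
# template in the canonical (articulated) frame
_FEMUR_TEMPLATE_TRANSLATION = np.array([40.0, -25.0, 60.0])


def _rotation_xyz(ax: float, ay: float, az: float) -> np.ndarray:
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


_FEMUR_TEMPLATE_ROTATION = _rotation_xyz(0.35, -0.2, 0.6)


def _canonical_points() -> np.ndarray:
    pts = np.zeros((11, 3))
    for i, ang in _RIM_ANGLES_DEG.items():
        t = np.deg2rad(ang)
        pts[i - 1] = (RIM_RADIUS_MM * np.cos(t), RIM_RADIUS_MM * np.sin(t), 0.0)
    for i, ang in _FOSSA_ANGLES_DEG.items():
        t = np.deg2rad(ang)
        pts[i - 1] = (FOSSA_RADIUS_MM * np.cos(t), FOSSA_RADIUS_MM * np.sin(t), -FOSSA_DEPTH_MM)
    return pts


def template_pair() -> tuple[LandmarkConfiguration, LandmarkConfiguration]:
    """Canonical acetabulum and femur templates (same spatial points).

    The femur template is the identical articulated point set expressed
    after a fixed rigid transform, so the two templates have equal
    centroid size and zero Procrustes shape distance by construction.
    """
    pts = _canonical_points()
    acet = LandmarkConfiguration("template_acetabulum", BoneType.ACETABULUM, Side.RIGHT, pts)
    fem_pts = pts @ _FEMUR_TEMPLATE_ROTATION.T + _FEMUR_TEMPLATE_TRANSLATION
    fem = LandmarkConfiguration("template_femur", BoneType.FEMUR, Side.RIGHT, fem_pts)
    return acet, fem


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic generator.

    FHD is drawn from the Normal(44.89, 3.83) mm size distribution of a
    typical adult human sample.  shape_sd controls smooth between-individual
    shape variation (dimensionless, in shape space); digitization_sd is
    iid per-coordinate placement noise in mm; oda_residual_sd (mm) is the
    scatter of ODA around its FHD regression line — the default, half the
    filter's 2.54 mm acceptance half-width, keeps the true-match metric
    rejection rate small but nonzero (about 4.6%).
    """

    n_individuals: int = 10
    fhd_mean: float = 44.89
    fhd_sd: float = 3.83
    shape_sd: float = 0.05
    digitization_sd: float = 0.5
    oda_residual_sd: float = 1.27
    left_fraction: float = 0.0
    drop_fraction: float = 0.0
    drop_fraction_acetabulum: float | None = None
    drop_fraction_femur: float | None = None
    n_populations: int = 1
    population_shift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("fhd_sd", "shape_sd", "digitization_sd", "oda_residual_sd",
                     "population_shift_sd"):
            if getattr(self, name) < 0:
                raise ComputationError(f"{name} must be >= 0")
        for name in ("left_fraction", "drop_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ComputationError(f"{name} must lie in [0, 1]")
        if self.n_individuals < 1:
            raise ComputationError("n_individuals must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """True pairings: individual id -> (acetabulum id, femur id); None = absent."""

    pairs: dict[str, tuple[str | None, str | None]]

    def acetabulum_to_femur(self) -> dict[str, str]:
        """Truth in evaluate_rankings form, for individuals with both bones."""
        return {a: f for a, f in self.pairs.values() if a is not None and f is not None}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation from a QR decomposition of Gaussian noise."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def _deform(points: np.ndarray, rng: np.random.Generator, shape_sd: float) -> np.ndarray:
    """Smooth low-dimensional individual shape deformation of the template.

    Anisotropic axis scaling + second-order rim ellipticity + rigid offset
    of the fossa/fovea block; every coefficient ~ Normal(0, shape_sd).
    Structured deviations keep matching surfaces identical in shape while
    making individuals mutually distinguishable — unstructured scatter is
    the role of digitization noise.
    """
    axis = 1.0 + rng.normal(0.0, shape_sd, size=3)
    e1, e2 = rng.normal(0.0, shape_sd, size=2)
    fossa_shift = rng.normal(0.0, shape_sd, size=3) * RIM_RADIUS_MM
    out = points * axis
    theta = np.arctan2(points[:, 1], points[:, 0])
    radial = 1.0 + e1 * np.cos(2 * theta) + e2 * np.sin(2 * theta)
    out[:, 0] *= radial
    out[:, 1] *= radial
    out[8:11] += fossa_shift
    return out


def generate_individual(
    params: SimulationParams, rng: np.random.Generator
) -> tuple[LandmarkConfiguration, LandmarkConfiguration, HipMeasurements]:
    """One simulated individual: acetabulum, femur, and hip measurements.

    The shape deformation and size scaling are shared by both bones;
    digitization noise and the rigid digitizer-frame motion are drawn
    independently per bone.
    """
    base = _deform(_canonical_points(), rng, params.shape_sd)
    fhd = float(rng.normal(params.fhd_mean, params.fhd_sd))
    base = base * (fhd / TEMPLATE_FHD_MM)

    bones = []
    for _ in range(2):
        pts = base + rng.normal(0.0, params.digitization_sd, size=base.shape)
        pts = pts @ _random_rotation(rng).T + rng.normal(0.0, 100.0, size=3)
        bones.append(pts)
    oda = float(_oda_mid(fhd) + rng.normal(0.0, params.oda_residual_sd))

    acet = LandmarkConfiguration("sim_acetabulum", BoneType.ACETABULUM, Side.RIGHT, bones[0])
    fem = LandmarkConfiguration("sim_femur", BoneType.FEMUR, Side.RIGHT, bones[1])
    return acet, fem, HipMeasurements(fhd=fhd, oda=oda)


def _oda_mid(fhd: float) -> float:
    """Point prediction of ODA from FHD under the filter's regression constants."""
    return DEFAULT_FILTER.intercept + DEFAULT_FILTER.slope * fhd


def generate_assemblage(params: SimulationParams) -> tuple[Assemblage, GroundTruth]:
    """A commingled assemblage of n individuals with its ground-truth table.

    Specimen ids carry a shuffled numbering so that id order does not
    encode the pairing.  Elements are independently recorded as left side
    (coordinates mirrored, side flag set) with probability left_fraction
    and omitted with probability drop_fraction (per-bone overrides
    available).  When ``n_populations > 1`` individuals are spread round-
    robin over populations, each with its own mean shape offset of
    magnitude population_shift_sd (a plain mean shift, with no claim of
    anatomical realism).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_individuals
    drop_a = (
        params.drop_fraction
        if params.drop_fraction_acetabulum is None
        else params.drop_fraction_acetabulum
    )
    drop_f = (
        params.drop_fraction if params.drop_fraction_femur is None else params.drop_fraction_femur
    )

    pop_offsets = [
        rng.normal(0.0, params.population_shift_sd, size=(11, 3)) * RIM_RADIUS_MM
        if params.n_populations > 1 and params.population_shift_sd > 0
        else np.zeros((11, 3))
        for _ in range(max(params.n_populations, 1))
    ]

    labels = rng.permutation(2 * n)
    configs: list[LandmarkConfiguration] = []
    measurements: dict[str, HipMeasurements] = {}
    truth: dict[str, str] = {}
    pairs: dict[str, tuple[str | None, str | None]] = {}

    for i in range(n):
        ind_id = f"IND{i + 1:03d}"
        pop = i % max(params.n_populations, 1)

        base = _deform(_canonical_points() + pop_offsets[pop], rng, params.shape_sd)
        fhd = float(rng.normal(params.fhd_mean, params.fhd_sd))
        base_scaled = base * (fhd / TEMPLATE_FHD_MM)
        oda = float(_oda_mid(fhd) + rng.normal(0.0, params.oda_residual_sd))

        ids: dict[BoneType, str | None] = {}
        for bone, prefix, meas, drop_p in (
            (BoneType.ACETABULUM, "ACE", HipMeasurements(oda=oda), drop_a),
            (BoneType.FEMUR, "FEM", HipMeasurements(fhd=fhd), drop_f),
        ):
            pts = base_scaled + rng.normal(0.0, params.digitization_sd, size=base.shape)
            pts = pts @ _random_rotation(rng).T + rng.normal(0.0, 100.0, size=3)
            is_left = bool(rng.random() < params.left_fraction)
            dropped = bool(rng.random() < drop_p)
            if dropped:
                ids[bone] = None
                continue
            k = labels[2 * i + (0 if bone is BoneType.ACETABULUM else 1)]
            spec_id = f"{prefix}{k:04d}"
            cfg = LandmarkConfiguration(spec_id, bone, Side.RIGHT, pts, individual_id=ind_id)
            if is_left:
                cfg = replace(mirror_configuration(cfg), specimen_id=spec_id)
            configs.append(cfg)
            measurements[spec_id] = meas
            truth[spec_id] = ind_id
            ids[bone] = spec_id
        pairs[ind_id] = (ids[BoneType.ACETABULUM], ids[BoneType.FEMUR])

    return Assemblage(configs, measurements, truth), GroundTruth(pairs)
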