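"""Landmark configurations, assemblages, and landmark-file I/O.

The matching method works on 11 homologous 3D landmarks digitized on each
articular surface of the hip joint: four fixed rim points (1-4), four rim
semilandmarks at the midpoints between them (5-8), and three points on the
acetabular fossa / fovea capitis (9-11).  The same numbering is used for
the acetabulum and for the femoral head, so landmark *i* on one bone is the
approximate spatial counterpart of landmark *i* on the other when the joint
is articulated.

Supported on-disk formats:

* IDAV Landmark ``.pts``-style text: whitespace-separated ``label x y z``
  lines (bare ``x y z`` also accepted); header/comment lines are skipped.
* a long-format CSV landmark table (one row per landmark) carrying a whole
  assemblage, with optional ground truth and linear measurements;
* TPS files with ``LM3`` blocks (read-only, for interoperability).

Coordinates are kept in millimetres exactly as read; no unit conversion is
attempted and no superimposition is ever applied by I/O code.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputFormatError, LandmarkParseError

N_LANDMARKS = 11

__all__ = [
    "N_LANDMARKS",
    "BoneType",
    "Side",
    "LandmarkConfiguration",
    "HipMeasurements",
    "Assemblage",
    "read_pts",
    "write_pts",
    "read_tps",
    "read_landmark_table",
    "write_landmark_table",
    "mirror_configuration",
    "validate_configuration",
]


class BoneType(str, enum.Enum):
    ACETABULUM = "acetabulum"
    FEMUR = "femur"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class HipMeasurements:
    """Linear hip-joint measurements in mm.

    fhd : maximum femoral head diameter (femora).
    oda : maximum diameter of the acetabulum (innominates).
    Either may be absent for a given specimen.
    """

    fhd: float | None = None
    oda: float | None = None

    def __post_init__(self):
        for name, v in (("fhd", self.fhd), ("oda", self.oda)):
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's ordered 3D landmarks plus identity metadata.

    ``coords`` holds the raw digitizer-frame coordinates (mm), one row per
    landmark in scheme order 1..11.  Construction coerces to a float array
    and freezes it; invariant violations (wrong count, non-finite values,
    degenerate geometry) are reported by :func:`validate_configuration`
    rather than raised here, so that defective files can be loaded and
    diagnosed.
    """

    specimen_id: str
    bone_type: BoneType
    side: Side
    coords: np.ndarray
    individual_id: str | None = None

    def __post_init__(self):
        arr = np.asarray(self.coords, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got shape {arr.shape}")
        arr = np.ascontiguousarray(arr)
        arr.setflags(write=False)
        object.__setattr__(self, "coords", arr)
        object.__setattr__(self, "bone_type", BoneType(self.bone_type))
        object.__setattr__(self, "side", Side(self.side))

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        return replace(self, coords=coords)


def mirror_configuration(cfg: LandmarkConfiguration) -> LandmarkConfiguration:
    """Reflect a configuration across the x=0 plane and flip its side flag.

    The landmark scheme is side-symmetric, so indices are unchanged.  Any
    single-axis reflection is equivalent up to a rotation, which the
    superimposition step removes; x is negated by convention.  The operation
    is an exact involution and preserves centroid size.
    """
    coords = cfg.coords * np.array([-1.0, 1.0, 1.0])
    flipped = Side.RIGHT if cfg.side == Side.LEFT else Side.LEFT
    return replace(cfg, coords=coords, side=flipped)


def validate_configuration(cfg: LandmarkConfiguration) -> list[str]:
    """Return machine-readable issue strings; empty iff all invariants hold.

    Issue codes (first token before ``:``): ``landmark-count``,
    ``non-finite``, ``degenerate-geometry``.
    """
    issues: list[str] = []
    n = cfg.n_landmarks
    if n != N_LANDMARKS:
        issues.append(f"landmark-count: expected {N_LANDMARKS}, found {n}")
    bad = ~np.isfinite(cfg.coords)
    if bad.any():
        for i in np.nonzero(bad.any(axis=1))[0]:
            issues.append(f"non-finite: landmark {i + 1}")
        return issues  # geometry checks meaningless with non-finite values
    if n >= 1:
        centered = cfg.coords - cfg.coords.mean(axis=0)
        # coincident or collinear point sets carry no usable shape
        if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(cfg.coords).max())) <= 1:
            issues.append("degenerate-geometry: landmarks coincident or collinear")
    return issues


# ---------------------------------------------------------------------------
# .pts-style text files


_LABEL_INDEX_RE = re.compile(r"(\d+)\s*$")


def _try_float(tok: str) -> float | None:
    try:
        return float(tok)
    except ValueError:
        return None


def read_pts(
    path: str | Path,
    *,
    bone_type: BoneType | str,
    side: Side | str,
    specimen_id: str | None = None,
    individual_id: str | None = None,
) -> LandmarkConfiguration:
    """Read one configuration from an IDAV Landmark ``.pts``-style file.

    Accepts ``label x y z`` and bare ``x y z`` lines; lines that carry no
    parseable coordinates (headers, comments, point counts) are skipped.
    A data-like line with a mix of numeric and non-numeric coordinate
    tokens raises a parse error naming the line.  Labels ending in an
    integer are mapped to scheme indices 1..11; otherwise file order is
    used.  Bone type and side are not stored in .pts files and must be
    supplied by the caller.
    """
    path = Path(path)
    points: list[tuple[int | None, np.ndarray]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        tokens = raw.split()
        if len(tokens) == 3:
            label, coord_toks = None, tokens
        elif len(tokens) == 4:
            label, coord_toks = tokens[0], tokens[1:]
        else:
            continue
        vals = [_try_float(t) for t in coord_toks]
        n_ok = sum(v is not None for v in vals)
        if n_ok == 0:
            continue  # header / comment line
        if n_ok < 3:
            bad = coord_toks[vals.index(None)]
            raise LandmarkParseError(f"non-numeric coordinate {bad!r}", lineno)
        idx = None
        if label is not None:
            m = _LABEL_INDEX_RE.search(label)
            if m:
                idx = int(m.group(1))
        points.append((idx, np.array(vals, dtype=float)))

    if len(points) != N_LANDMARKS:
        raise InputFormatError(
            f"{path.name}: expected {N_LANDMARKS} landmarks, found {len(points)}"
        )
    indices = [i for i, _ in points]
    if all(i is not None for i in indices) and sorted(indices) == list(
        range(1, N_LANDMARKS + 1)
    ):
        order = np.argsort(indices)
    else:
        order = np.arange(N_LANDMARKS)
    coords = np.stack([points[i][1] for i in order])
    return LandmarkConfiguration(
        specimen_id=specimen_id or path.stem,
        bone_type=BoneType(bone_type),
        side=Side(side),
        coords=coords,
        individual_id=individual_id,
    )


def write_pts(cfg: LandmarkConfiguration, path: str | Path, *, precision: int = 6) -> None:
    """Write a configuration as ``Lmk_i x y z`` lines (fixed precision)."""
    lines = [
        f"Lmk_{i + 1} {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}"
        for i, (x, y, z) in enumerate(cfg.coords)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TPS (LM3 blocks, read-only)


def read_tps(
    path: str | Path,
    *,
    bone_type: BoneType | str,
    side: Side | str,
) -> list[LandmarkConfiguration]:
    """Read all LM3 blocks of a TPS file as configurations.

    Specimen ids come from ``ID=`` records when present, else the block
    ordinal.  All configurations receive the supplied bone type and side.
    """
    path = Path(path)
    configs: list[LandmarkConfiguration] = []
    block: list[np.ndarray] | None = None
    expected = 0
    spec_id: str | None = None

    def flush(ordinal: int):
        nonlocal block, spec_id
        if block is None:
            return
        if len(block) != expected:
            raise InputFormatError(
                f"{path.name}: LM3 block declared {expected} points, found {len(block)}"
            )
        configs.append(
            LandmarkConfiguration(
                specimen_id=spec_id or f"{path.stem}_{ordinal}",
                bone_type=BoneType(bone_type),
                side=Side(side),
                coords=np.stack(block),
            )
        )
        block, spec_id = None, None

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM3"):
            flush(len(configs))
            expected = int(line.split("=", 1)[1])
            block = []
        elif upper.startswith("ID"):
            spec_id = line.split("=", 1)[1].strip()
        elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
            continue  # IMAGE=, SCALE=, ...
        elif block is not None:
            vals = [_try_float(t) for t in line.split()]
            if len(vals) != 3 or any(v is None for v in vals):
                raise LandmarkParseError(f"bad LM3 coordinate line {line!r}", lineno)
            block.append(np.array(vals, dtype=float))
    flush(len(configs))
    return configs


# ---------------------------------------------------------------------------
# Assemblages and the CSV landmark table


@dataclass
class Assemblage:
    """A commingled collection of configurations with optional metadata.

    ``measurements`` maps specimen_id to linear measurements; ``truth`` maps
    specimen_id to the individual it belongs to (ground truth, available for
    simulated or artificially commingled material).
    """

    configurations: list[LandmarkConfiguration]
    measurements: dict[str, HipMeasurements] = field(default_factory=dict)
    truth: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = [c.specimen_id for c in self.configurations]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise InputFormatError(f"duplicate specimen ids: {sorted(dupes)}")
        unknown = set(self.truth) - set(ids)
        if unknown:
            raise InputFormatError(f"truth refers to unknown specimens: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.configurations)

    def __getitem__(self, specimen_id: str) -> LandmarkConfiguration:
        for c in self.configurations:
            if c.specimen_id == specimen_id:
                return c
        raise KeyError(specimen_id)

    @property
    def acetabula(self) -> list[LandmarkConfiguration]:
        return [c for c in self.configurations if c.bone_type is BoneType.ACETABULUM]

    @property
    def femora(self) -> list[LandmarkConfiguration]:
        return [c for c in self.configurations if c.bone_type is BoneType.FEMUR]

    def true_pairs(self) -> dict[str, str]:
        """Map each acetabulum to its true femur, for individuals with both."""
        by_ind: dict[str, dict[BoneType, str]] = {}
        for c in self.configurations:
            ind = self.truth.get(c.specimen_id)
            if ind is not None:
                by_ind.setdefault(ind, {})[c.bone_type] = c.specimen_id
        return {
            bones[BoneType.ACETABULUM]: bones[BoneType.FEMUR]
            for bones in by_ind.values()
            if BoneType.ACETABULUM in bones and BoneType.FEMUR in bones
        }

    def normalized_to_right(self) -> "Assemblage":
        """Mirror every left-side configuration to right-side convention."""
        configs = [
            mirror_configuration(c) if c.side is Side.LEFT else c
            for c in self.configurations
        ]
        return Assemblage(configs, dict(self.measurements), dict(self.truth))


_TABLE_COLUMNS = ["specimen_id", "bone_type", "side", "landmark", "x", "y", "z"]


def read_landmark_table(path: str | Path) -> Assemblage:
    """Read an assemblage from a long-format CSV landmark table.

    Required columns: specimen_id, bone_type, side, landmark, x, y, z.
    Optional: individual_id (ground truth), fhd, oda (mm).  Each specimen
    must contribute exactly one row per landmark index 1..11 and consistent
    metadata across its rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"landmark table missing columns: {missing}")

    configs: list[LandmarkConfiguration] = []
    measurements: dict[str, HipMeasurements] = {}
    truth: dict[str, str] = {}
    for spec_id, grp in df.groupby("specimen_id", sort=False):
        for col in ("bone_type", "side"):
            if grp[col].nunique() > 1:
                raise InputFormatError(
                    f"duplicate specimen id {spec_id!r}: inconsistent {col} values "
                    f"{sorted(grp[col].unique())}"
                )
        idx = grp["landmark"].astype(int)
        if idx.duplicated().any():
            raise InputFormatError(
                f"specimen {spec_id!r}: repeated landmark indices "
                f"{sorted(idx[idx.duplicated()].unique())}"
            )
        absent = sorted(set(range(1, N_LANDMARKS + 1)) - set(idx))
        if absent:
            raise InputFormatError(f"specimen {spec_id!r}: missing landmark indices {absent}")
        grp = grp.sort_values("landmark")
        coords = grp[["x", "y", "z"]].to_numpy(dtype=float)
        individual = None
        if "individual_id" in grp.columns:
            vals = grp["individual_id"].dropna().unique()
            if len(vals):
                individual = str(vals[0])
                truth[str(spec_id)] = individual
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(spec_id),
                bone_type=BoneType(str(grp["bone_type"].iloc[0])),
                side=Side(str(grp["side"].iloc[0])),
                coords=coords,
                individual_id=individual,
            )
        )
        m = {}
        for col in ("fhd", "oda"):
            if col in grp.columns:
                vals = grp[col].dropna().unique()
                if len(vals):
                    m[col] = float(vals[0])
        if m:
            measurements[str(spec_id)] = HipMeasurements(**m)
    return Assemblage(configs, measurements, truth)


def write_landmark_table(
    assemblage: Assemblage, path: str | Path, *, precision: int = 9
) -> None:
    """Write an assemblage as a CSV landmark table (read_landmark_table inverse)."""
    rows = []
    for cfg in assemblage.configurations:
        m = assemblage.measurements.get(cfg.specimen_id)
        ind = assemblage.truth.get(cfg.specimen_id, cfg.individual_id)
        for i, (x, y, z) in enumerate(cfg.coords, start=1):
            rows.append(
                {
                    "specimen_id": cfg.specimen_id,
                    "bone_type": cfg.bone_type.value,
                    "side": cfg.side.value,
                    "landmark": i,
                    "x": round(float(x), precision),
                    "y": round(float(y), precision),
                    "z": round(float(z), precision),
                    "individual_id": ind,
                    "fhd": None if m is None else m.fhd,
                    "oda": None if m is None else m.oda,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=f"%.{precision}g")
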