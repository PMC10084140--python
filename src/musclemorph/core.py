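"""Shared domain types and error taxonomy.

All geometry lives in world millimetres. Surface meshes are
:class:`trimesh.Trimesh` objects that are expected to be watertight and
outward-oriented; the dataclasses here carry everything else the pipeline
passes between stages (landmarks, rigid transforms, per-case metrics,
subject metadata).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------- #
# errors
# --------------------------------------------------------------------------- #

class MuscleMorphError(Exception):
    """Base class for package errors."""


class ParameterError(MuscleMorphError, ValueError):
    """Invalid, non-finite or out-of-range parameter."""


class DegenerateGeometryError(MuscleMorphError):
    """Geometry too thin, self-intersecting or otherwise unusable."""


class EmptySegmentationError(MuscleMorphError):
    """Requested label absent from a label volume."""


class EmptySectionError(MuscleMorphError):
    """A cutting plane does not intersect the surface."""


class GridMismatchError(MuscleMorphError):
    """Binary occupancies do not share origin/spacing/shape."""


class UndefinedRatioError(MuscleMorphError):
    """Overlap ratio of two empty occupancies is undefined."""


class DegenerateLandmarkError(MuscleMorphError):
    """Landmark configuration is collinear or otherwise rank deficient."""


class CorrespondenceError(MuscleMorphError):
    """Landmark labels of the two sets do not match."""


class DesignError(MuscleMorphError):
    """Statistical design is unbalanced or incomplete."""


# --------------------------------------------------------------------------- #
# landmarks
# --------------------------------------------------------------------------- #

LANDMARK_LABELS = (
    "proximal_1", "proximal_2", "proximal_3",
    "distal_1", "distal_2", "distal_3",
)


@dataclass
class LandmarkSet:
    """Six labelled musculotendinous-junction points (mm).

    Three points sit on the proximal MTJ and three on the distal MTJ;
    correspondence between two sets is by label, never by proximity.
    """

    points: np.ndarray  # (6, 3) float, ordered as LANDMARK_LABELS
    labels: tuple = LANDMARK_LABELS

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (6, 3):
            raise ParameterError(
                f"landmark set needs exactly 6 points, got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("landmark coordinates must be finite")
        if tuple(self.labels) != LANDMARK_LABELS:
            # allow any order on input but store canonically
            order = [list(self.labels).index(lbl) for lbl in LANDMARK_LABELS]
            self.points = self.points[order]
            self.labels = LANDMARK_LABELS

    @property
    def proximal(self) -> np.ndarray:
        return self.points[:3]

    @property
    def distal(self) -> np.ndarray:
        return self.points[3:]

    def transformed(self, func) -> "LandmarkSet":
        """Return a copy with ``func`` applied to the (6, 3) coordinates."""
        return LandmarkSet(np.asarray(func(self.points.copy()), dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels,
             "x_mm": self.points[:, 0],
             "y_mm": self.points[:, 1],
             "z_mm": self.points[:, 2]})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path)
        missing = set(LANDMARK_LABELS) - set(df["label"])
        if missing:
            raise CorrespondenceError(f"landmark CSV missing labels: {sorted(missing)}")
        df = df.set_index("label").loc[list(LANDMARK_LABELS)]
        return cls(df[["x_mm", "y_mm", "z_mm"]].to_numpy(float))


# --------------------------------------------------------------------------- #
# rigid transform
# --------------------------------------------------------------------------- #

@dataclass
class RigidTransform:
    """Proper rigid map x -> R x + t (rotation + translation, no reflection)."""

    rotation: np.ndarray     # (3, 3)
    translation: np.ndarray  # (3,)
    residual_rms_mm: float = 0.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ParameterError("rotation is not orthonormal within 1e-9")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ParameterError("rotation determinant must be +1 (no reflection)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


# --------------------------------------------------------------------------- #
# metrics containers
# --------------------------------------------------------------------------- #

@dataclass
class SimilarityReport:
    """Bilateral shape-similarity metrics on an aligned pair."""

    jaccard: float
    rmse_mm: float
    hausdorff_mm: float
    hausdorff_location: np.ndarray  # (3,) mm, sample attaining the max
    hausdorff_direction: str = ""   # "a_to_b" or "b_to_a"
    voxel_size_mm: float = float("nan")
    sample_count: int = 0

    def __post_init__(self):
        self.hausdorff_location = np.asarray(self.hausdorff_location, float).reshape(3)
        if not (-1e-9 <= self.jaccard <= 1 + 1e-9):
            raise ParameterError(f"jaccard out of [0,1]: {self.jaccard}")

    def to_row(self, subject_id: str = "") -> dict:
        return {
            "subject_id": subject_id,
            "jaccard": self.jaccard,
            "rmse_mm": self.rmse_mm,
            "hausdorff_mm": self.hausdorff_mm,
            "hx": self.hausdorff_location[0],
            "hy": self.hausdorff_location[1],
            "hz": self.hausdorff_location[2],
            "voxel_size_mm": self.voxel_size_mm,
            "sample_count": self.sample_count,
        }


REGIONS = ("proximal", "middle", "distal")


@dataclass
class RegionRecord:
    peak_csa_cm2: float
    volume_cm3: float
    peak_csa_cm2_per_kg_m: float = float("nan")
    volume_cm3_per_kg_m: float = float("nan")


@dataclass
class MorphologyRecord:
    """Whole-muscle and regional discrete morphology.

    Raw units follow the field convention (cm, cm^2, cm^3); normalized
    variants divide by limb length (m) for length and mass x limb length
    (kg.m) for peak CSA and volume.
    """

    length_cm: float
    peak_csa_cm2: float
    peak_csa_station_mm: float
    volume_cm3: float
    regions: Mapping[str, RegionRecord]
    length_cm_per_m: float = float("nan")
    peak_csa_cm2_per_kg_m: float = float("nan")
    volume_cm3_per_kg_m: float = float("nan")

    def to_row(self, subject_id: str = "", limb: str = "") -> dict:
        row = {
            "subject_id": subject_id,
            "limb": limb,
            "length_cm": self.length_cm,
            "peak_csa_cm2": self.peak_csa_cm2,
            "peak_csa_station_mm": self.peak_csa_station_mm,
            "volume_cm3": self.volume_cm3,
            "length_cm_per_m": self.length_cm_per_m,
            "peak_csa_cm2_per_kg_m": self.peak_csa_cm2_per_kg_m,
            "volume_cm3_per_kg_m": self.volume_cm3_per_kg_m,
        }
        for name in REGIONS:
            reg = self.regions[name]
            row[f"{name}_peak_csa_cm2"] = reg.peak_csa_cm2
            row[f"{name}_volume_cm3"] = reg.volume_cm3
            row[f"{name}_peak_csa_cm2_per_kg_m"] = reg.peak_csa_cm2_per_kg_m
            row[f"{name}_volume_cm3_per_kg_m"] = reg.volume_cm3_per_kg_m
        return row


@dataclass
class SubjectMeta:
    """Per-subject metadata consumed by normalization and group statistics."""

    subject_id: str
    group: str                 # "control" | "aclr"
    mass_kg: float
    limb_length_m: float
    regenerated: bool = False

    def __post_init__(self):
        if not (self.mass_kg > 0 and np.isfinite(self.mass_kg)):
            raise ParameterError("mass_kg must be positive")
        if not (self.limb_length_m > 0 and np.isfinite(self.limb_length_m)):
            raise ParameterError("limb_length_m must be positive")
        self.group = str(self.group).lower()


@dataclass
class SubjectCase:
    """One subject: bilateral muscle pair, landmarks and metadata.

    ``sides`` maps a side label to a watertight mesh (or a label volume,
    converted at pipeline entry); ``reference_side`` is the uninjured limb
    for reconstructed subjects (the right limb in controls by convention).
    """

    subject_id: str
    sides: Mapping[str, object]            # side label -> Trimesh | LabelVolume
    landmarks: Mapping[str, LandmarkSet]   # side label -> LandmarkSet
    meta: SubjectMeta
    reference_side: str = "right"
    truth: Mapping[str, float] | None = None  # generator ground truth, if synthetic

    def __post_init__(self):
        if len(self.sides) != 2:
            raise ParameterError("a subject case needs exactly two limbs")
        if set(self.sides) != set(self.landmarks):
            raise CorrespondenceError("mesh and landmark side labels differ")
        if self.reference_side not in self.sides:
            raise ParameterError(
                f"reference side {self.reference_side!r} not among {set(self.sides)}")

    @property
    def moving_side(self) -> str:
        return next(s for s in self.sides if s != self.reference_side)


@dataclass
class CaseResult:
    """Everything the pipeline reports for one subject."""

    subject_id: str
    similarity: SimilarityReport
    morphology: Mapping[str, MorphologyRecord]  # side label -> record (unscaled)
    scale_factor: float
    registration_rms_mm: float
    hausdorff_region: str                       # proximal | middle | distal
    reference_side: str
    moving_side: str
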