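"""Core data containers shared across the pipeline.

World coordinates are RAS millimetres throughout; voxel grids map index
``(i, j, k)`` to world space through ``origin + index * spacing``
(voxel-centre convention, axis-aligned affine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class GridMismatchError(ValueError):
    """Two gridded objects do not share shape/spacing/origin."""


class DegenerateInputError(ValueError):
    """Input lacks the variability or size the operation requires."""


# ---------------------------------------------------------------------------
# Volumes and masks
# ---------------------------------------------------------------------------


@dataclass
class Volume:
    """A 3-D scalar grid with physical spacing and origin.

    Parameters
    ----------
    data
        3-D array of intensities (or 0/1 labels for masks).
    spacing
        Millimetres per voxel along each axis, all positive.
    origin
        World coordinates (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __init__(self, data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
        data = np.asarray(data)
        if data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got shape {data.shape}")
        spacing = np.asarray(spacing, dtype=float)
        origin = np.asarray(origin, dtype=float)
        if spacing.shape != (3,) or origin.shape != (3,):
            raise ValueError("spacing and origin must be length-3")
        if not np.all(spacing > 0):
            raise ValueError(f"spacing must be positive, got {spacing}")
        if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite values")
        self.data = data
        self.spacing = spacing
        self.origin = origin

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal, RAS)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def grid_compatible(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_compatible(self, other: "Volume", what: str = "volumes") -> None:
        if not self.grid_compatible(other):
            raise GridMismatchError(
                f"{what} are not grid-compatible: "
                f"{self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def indices_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (N x 3) to world mm."""
        return np.asarray(indices, dtype=float) * self.spacing + self.origin

    def world_to_indices(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same grid, new voxel values."""
        return Volume(data, self.spacing.copy(), self.origin.copy())


def as_mask(volume: Volume) -> Volume:
    """Coerce a volume to boolean voxel values on the same grid."""
    return volume.with_data(volume.data.astype(bool))


# ---------------------------------------------------------------------------
# Point clouds
# ---------------------------------------------------------------------------


@dataclass
class PointCloud:
    """N points in world mm with optional unit normals and integer labels.

    ``labels`` carries per-point branch identity where known; -1 marks
    synthetic outlier points. ``normals`` rows may be NaN where a normal
    could not be estimated (fewer than 3 neighbours).
    """

    points: np.ndarray
    normals: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be N x 3, got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)
            if self.normals.shape != self.points.shape:
                raise ValueError("normals must match points shape")
            norms = np.linalg.norm(self.normals, axis=1)
            valid = np.isfinite(norms)
            if np.any(np.abs(norms[valid] - 1.0) > 1e-6):
                raise ValueError("normals must be unit length (or NaN if invalid)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (len(self.points),):
                raise ValueError("labels must be one per point")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def valid_normal_mask(self) -> np.ndarray:
        if self.normals is None:
            return np.zeros(len(self), dtype=bool)
        return np.all(np.isfinite(self.normals), axis=1)

    def select(self, index) -> "PointCloud":
        return PointCloud(
            self.points[index],
            None if self.normals is None else self.normals[index],
            None if self.labels is None else self.labels[index],
        )

    def transformed(self, t: "SimilarityTransform") -> "PointCloud":
        normals = None
        if self.normals is not None:
            normals = self.normals @ t.rotation.T  # rotation preserves unit length
        return PointCloud(t.apply(self.points), normals,
                          None if self.labels is None else self.labels.copy())


# ---------------------------------------------------------------------------
# Similarity transforms
# ---------------------------------------------------------------------------


@dataclass
class SimilarityTransform:
    """x -> scale * R @ x + t with R a proper rotation and scale > 0."""

    scale: float = 1.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.scale = float(self.scale)
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.scale * pts @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        r_inv = self.rotation.T
        s_inv = 1.0 / self.scale
        return SimilarityTransform(s_inv, r_inv, -s_inv * r_inv @ self.translation)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equal to applying ``other`` first, then self."""
        return SimilarityTransform(
            self.scale * other.scale,
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
        )

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(d["scale"], np.asarray(d["rotation"]), np.asarray(d["translation"]))


# ---------------------------------------------------------------------------
# Camera trajectories
# ---------------------------------------------------------------------------


@dataclass
class CameraTrajectory:
    """Ordered endoscope poses: positions in mm, world-from-camera quaternions.

    Quaternions are stored ``(w, x, y, z)`` and unit-normalised; the camera
    viewing direction is the rotated +z axis.
    """

    frame_ids: np.ndarray
    positions: np.ndarray
    quaternions: np.ndarray

    def __post_init__(self):
        self.frame_ids = np.asarray(self.frame_ids, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.quaternions = np.asarray(self.quaternions, dtype=float).reshape(-1, 4)
        n = len(self.frame_ids)
        if len(self.positions) != n or len(self.quaternions) != n:
            raise ValueError("frame_ids, positions, quaternions must align")
        if n > 1 and not np.all(np.diff(self.frame_ids) > 0):
            raise ValueError("frame_ids must be strictly increasing")
        norms = np.linalg.norm(self.quaternions, axis=1)
        if n and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternions must be unit length")

    def __len__(self) -> int:
        return len(self.frame_ids)

    def view_directions(self) -> np.ndarray:
        """Unit viewing direction (camera +z in world frame) per pose."""
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_quat(self.quaternions[:, [1, 2, 3, 0]])
        return rot.apply(np.tile([0.0, 0.0, 1.0], (len(self), 1)))


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class RegistrationResult:
    """Outcome of a (global or refined) alignment plus its quality metrics.

    ``inlier_rmse`` is the RMS nearest-neighbour distance over source points
    whose nearest target point lies within ``correspondence_threshold`` mm;
    ``fitness`` is the inlier share of the source cloud. With zero inliers
    the RMSE is reported as 0.0 and ``zero_inliers`` is set.
    """

    transform: SimilarityTransform
    inlier_rmse: float
    inlier_count: int
    total_source_points: int
    correspondence_threshold: float
    n_iterations: int = 0
    converged: bool = True
    objective_history: Optional[list] = None

    @property
    def fitness(self) -> float:
        if self.total_source_points == 0:
            return 0.0
        return self.inlier_count / self.total_source_points

    @property
    def zero_inliers(self) -> bool:
        return self.inlier_count == 0

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.to_dict(),
            "inlier_rmse": self.inlier_rmse,
            "inlier_count": int(self.inlier_count),
            "total_source_points": int(self.total_source_points),
            "fitness": self.fitness,
            "correspondence_threshold": self.correspondence_threshold,
            "zero_inliers": self.zero_inliers,
        }


@dataclass
class CoverageReport:
    """Share of the CT-model surface within ``tau_mm`` of observed points."""

    covered_fraction: float
    tau_mm: float
    n_model_points: int
    per_branch: Optional[dict] = None

    def to_dict(self) -> dict:
        d = {
            "covered_fraction": self.covered_fraction,
            "tau_mm": self.tau_mm,
            "n_model_points": int(self.n_model_points),
        }
        if self.per_branch is not None:
            d["per_branch"] = {str(k): v for k, v in self.per_branch.items()}
        return d
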