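"""Endoscope localization in the CT frame and coverage assessment.

Once the reconstruction-to-CT transform is known, the per-frame SfM camera
poses map into the CT model, giving an endoscope position estimate for
every frame. Coverage — the share of the CT-model surface the endoscope
actually visualized — is the clinically relevant summary: unvisited
branches are where residual stones hide.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .types import (
    CameraTrajectory,
    CoverageReport,
    DegenerateInputError,
    PointCloud,
    SimilarityTransform,
)

#: default coverage distance threshold: twice the 1 mm model sampling pitch
DEFAULT_TAU_MM = 2.0


def transform_trajectory(
    traj: CameraTrajectory, t: SimilarityTransform
) -> CameraTrajectory:
    """Map a trajectory through a similarity transform.

    Positions follow ``p -> s R p + t``; orientations are rotated by the
    transform's rotation part (scale does not affect directions) and
    renormalized. Frame ids and ordering are preserved.
    """
    rot = Rotation.from_matrix(t.rotation)
    q = Rotation.from_quat(traj.quaternions[:, [1, 2, 3, 0]])
    out = (rot * q).as_quat()[:, [3, 0, 1, 2]]
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return CameraTrajectory(
        frame_ids=traj.frame_ids.copy(),
        positions=t.apply(traj.positions),
        quaternions=out,
    )


def coverage_fraction(
    model_cloud: PointCloud,
    observed_cloud: PointCloud,
    tau_mm: float = DEFAULT_TAU_MM,
    branch_labels: Optional[np.ndarray] = None,
) -> CoverageReport:
    """Fraction of CT-model surface points within ``tau_mm`` of the
    registered observation cloud, optionally broken down per branch.

    ``branch_labels`` (one per model point) enables the per-branch report;
    an empty observed cloud yields coverage 0 everywhere.
    """
    if tau_mm <= 0:
        raise ValueError("tau_mm must be positive")
    if len(model_cloud) == 0:
        raise DegenerateInputError("model cloud is empty")
    if branch_labels is not None:
        branch_labels = np.asarray(branch_labels)
        if len(branch_labels) != len(model_cloud):
            raise ValueError("branch_labels must be one per model point")

    if len(observed_cloud) == 0:
        covered = np.zeros(len(model_cloud), dtype=bool)
    else:
        tree = cKDTree(observed_cloud.points)
        dist, _ = tree.query(model_cloud.points)
        covered = dist <= tau_mm

    per_branch: Optional[Dict[int, float]] = None
    if branch_labels is not None:
        per_branch = {
            int(lab): float(covered[branch_labels == lab].mean())
            for lab in np.unique(branch_labels)
        }
    return CoverageReport(
        covered_fraction=float(covered.mean()),
        tau_mm=tau_mm,
        n_model_points=len(model_cloud),
        per_branch=per_branch,
    )


def trajectory_error(
    estimated: CameraTrajectory, truth: CameraTrajectory
) -> Dict[str, object]:
    """Per-frame and summary errors between two trajectories.

    Frames are matched by ``frame_id`` (their intersection; disjoint sets
    are an error). Position error is Euclidean distance in mm; orientation
    error is the geodesic angle on the rotation group in degrees, with the
    quaternion sign ambiguity removed via the absolute dot product.
    """
    common, ia, ib = np.intersect1d(
        estimated.frame_ids, truth.frame_ids, return_indices=True
    )
    if len(common) == 0:
        raise ValueError("estimated and truth trajectories share no frame_ids")

    pos_err = np.linalg.norm(
        estimated.positions[ia] - truth.positions[ib], axis=1
    )
    dots = np.abs(np.sum(estimated.quaternions[ia] * truth.quaternions[ib], axis=1))
    ang_err = np.rad2deg(2.0 * np.arccos(np.clip(dots, -1.0, 1.0)))

    def summary(err: np.ndarray) -> Dict[str, float]:
        return {
            "mean": float(np.mean(err)),
            "median": float(np.median(err)),
            "max": float(np.max(err)),
            "rmse": float(np.sqrt(np.mean(err**2))),
        }

    return {
        "frame_ids": common,
        "position_error_mm": pos_err,
        "orientation_error_deg": ang_err,
        "position": summary(pos_err),
        "orientation": summary(ang_err),
        "n_frames": int(len(common)),
    }
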