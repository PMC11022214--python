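"""Readers and writers for the pipeline's on-disk artifacts.

Formats: NIfTI for volumes/masks (axis-aligned RAS affine, mm), PLY for
point clouds and meshes (OBJ also accepted for meshes), CSV for camera
trajectories and manual correspondences, JSON for similarity transforms
and metrics, and read-only COLMAP ``images.txt`` for externally produced
camera poses.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple, Union

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .types import CameraTrajectory, PointCloud, SimilarityTransform, Volume

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A file could not be parsed; the message locates the problem."""


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------


def save_volume(volume: Volume, path: PathLike, as_mask: bool = False) -> None:
    """Write a volume as NIfTI; masks are stored as uint8 {0, 1}."""
    data = volume.data
    if as_mask or data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), volume.affine)
    nib.save(img, str(path))


def load_volume(path: PathLike, as_mask: bool = False) -> Volume:
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ParseError(
            f"{path}: only axis-aligned (diagonal) affines are supported"
        )
    spacing = np.diag(aff[:3, :3])
    if np.any(spacing <= 0):
        raise ParseError(f"{path}: affine has non-positive voxel spacing")
    data = np.asarray(img.dataobj)
    if as_mask:
        data = data.astype(bool)
    return Volume(data, spacing, aff[:3, 3])


# ---------------------------------------------------------------------------
# Point clouds and meshes (PLY / OBJ)
# ---------------------------------------------------------------------------


def _check_ply_header(path: Path) -> None:
    """Light validation so truncated headers fail with a clear message."""
    with open(path, "rb") as fh:
        head = fh.read(4096)
    if not head.startswith(b"ply"):
        raise ParseError(f"{path}: not a PLY file (missing 'ply' magic)")
    if b"end_header" not in head:
        raise ParseError(f"{path}: truncated PLY header (missing 'end_header')")
    if b"element vertex" not in head:
        raise ParseError(f"{path}: PLY header missing 'element vertex'")


def save_point_cloud(cloud: PointCloud, path: PathLike) -> None:
    """Write point coordinates as binary PLY. Labels, when present, are
    written alongside as ``<stem>.labels.csv`` so branch identity survives
    the round trip."""
    path = Path(path)
    trimesh.PointCloud(cloud.points).export(str(path))
    if cloud.labels is not None:
        pd.DataFrame({"label": cloud.labels}).to_csv(
            path.with_suffix(".labels.csv"), index=False
        )


def load_point_cloud(path: PathLike) -> PointCloud:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _check_ply_header(path)
    try:
        obj = trimesh.load(str(path))
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"{path}: failed to parse point cloud: {exc}") from exc
    pts = np.asarray(obj.vertices, dtype=float)
    labels = None
    label_file = path.with_suffix(".labels.csv")
    if label_file.exists():
        labels = pd.read_csv(label_file)["label"].to_numpy()
        if len(labels) != len(pts):
            raise ParseError(f"{label_file}: label count does not match points")
    return PointCloud(pts, labels=labels)


def save_mesh(mesh: trimesh.Trimesh, path: PathLike) -> None:
    mesh.export(str(path))


def load_mesh(path: PathLike) -> trimesh.Trimesh:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _check_ply_header(path)
    try:
        mesh = trimesh.load(str(path), force="mesh")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: failed to parse mesh: {exc}") from exc
    return mesh


# ---------------------------------------------------------------------------
# Trajectories (CSV and COLMAP images.txt)
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = ["frame_id", "x", "y", "z", "qw", "qx", "qy", "qz"]


def save_trajectory(traj: CameraTrajectory, path: PathLike) -> None:
    df = pd.DataFrame(
        np.column_stack([traj.frame_ids, traj.positions, traj.quaternions]),
        columns=_TRAJ_COLUMNS,
    )
    df["frame_id"] = df["frame_id"].astype(int)
    df.to_csv(path, index=False)


def load_trajectory(path: PathLike) -> CameraTrajectory:
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: trajectory CSV missing columns {missing}")
    return CameraTrajectory(
        frame_ids=df["frame_id"].to_numpy(int),
        positions=df[["x", "y", "z"]].to_numpy(float),
        quaternions=df[["qw", "qx", "qy", "qz"]].to_numpy(float),
    )


def load_colmap_images(path: PathLike) -> CameraTrajectory:
    """Read camera poses from a COLMAP ``images.txt``.

    COLMAP stores, per image, the world-to-camera rotation as a quaternion
    ``QW QX QY QZ`` and translation ``TX TY TZ`` (so a world point X maps
    to camera coordinates R X + t). The returned trajectory converts these
    to world-frame camera centres ``-R^T t`` and world-from-camera
    orientations (the conjugate quaternion), sorted by image id. The
    POINTS2D line following each pose line is ignored.
    """
    records = []
    with open(path) as fh:
        expecting_points = False
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if expecting_points:
                expecting_points = False
                continue
            parts = line.split()
            if len(parts) < 10:
                raise ParseError(
                    f"{path}:{lineno}: expected IMAGE_ID QW QX QY QZ TX TY TZ "
                    f"CAMERA_ID NAME, got {len(parts)} fields"
                )
            try:
                image_id = int(parts[0])
                qw, qx, qy, qz = (float(v) for v in parts[1:5])
                tx, ty, tz = (float(v) for v in parts[5:8])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric pose field") from exc
            records.append((image_id, qw, qx, qy, qz, tx, ty, tz))
            expecting_points = True
    if not records:
        raise ParseError(f"{path}: no image records found")

    records.sort(key=lambda r: r[0])
    from scipy.spatial.transform import Rotation

    ids = np.array([r[0] for r in records], dtype=int)
    quats_wc = np.array([r[1:5] for r in records])  # world->camera, (w,x,y,z)
    trans = np.array([r[5:8] for r in records])
    rot_wc = Rotation.from_quat(quats_wc[:, [1, 2, 3, 0]])
    centres = -rot_wc.inv().apply(trans)
    q_cw = rot_wc.inv().as_quat()[:, [3, 0, 1, 2]]
    q_cw /= np.linalg.norm(q_cw, axis=1, keepdims=True)
    return CameraTrajectory(frame_ids=ids, positions=centres, quaternions=q_cw)


# ---------------------------------------------------------------------------
# Transforms, correspondences, metrics
# ---------------------------------------------------------------------------


def save_transform(transform: SimilarityTransform, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(transform.to_dict(), fh, indent=2)


def load_transform(path: PathLike) -> SimilarityTransform:
    with open(path) as fh:
        d = json.load(fh)
    try:
        return SimilarityTransform.from_dict(d)
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: invalid transform JSON: {exc}") from exc


_CORR_COLUMNS = ["source_x", "source_y", "source_z", "target_x", "target_y", "target_z"]


def load_correspondences(path: PathLike) -> Tuple[np.ndarray, np.ndarray]:
    """Manually picked point pairs as a CSV with columns
    source_x..target_z; returns (K x 3 source, K x 3 target)."""
    df = pd.read_csv(path)
    missing = [c for c in _CORR_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: correspondence CSV missing columns {missing}")
    return (
        df[_CORR_COLUMNS[:3]].to_numpy(float),
        df[_CORR_COLUMNS[3:]].to_numpy(float),
    )


def save_json(obj: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    raise TypeError(f"not JSON serializable: {type(value)}")
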