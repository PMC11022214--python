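"""CT-side 3-D model: isosurface meshing, normal-offset dilation, sampling.

The collecting-system mask becomes a triangulated surface via marching
cubes, is optionally pushed outward along vertex normals to mimic the
intra-operative distension of the kidney under irrigation, and is sampled
area-uniformly into a point cloud for registration.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .types import DegenerateInputError, PointCloud, Volume


def extract_isosurface(
    mask: Volume, level: float = 0.5, smooth_sigma: float = 0.0
) -> trimesh.Trimesh:
    """Marching-cubes surface of a binary mask, vertices in world mm.

    ``smooth_sigma`` (voxels) optionally Gaussian-smooths the 0/1 occupancy
    field before contouring; on binary data the raw isosurface sits on a
    half-voxel staircase, and a small amount of smoothing recovers a
    sub-voxel-accurate surface at the cost of slight rounding at high
    curvature. Normals are oriented outward.
    """
    data = mask.data.astype(float)
    if not (data.max() > level > data.min()):
        raise DegenerateInputError(
            "mask must contain voxels on both sides of the iso-level "
            f"(level={level}, data range [{data.min()}, {data.max()}])"
        )
    if smooth_sigma > 0:
        data = ndimage.gaussian_filter(data, sigma=smooth_sigma)
        if not (data.max() > level > data.min()):
            raise DegenerateInputError(
                "smoothing erased the iso-level crossing; lower smooth_sigma"
            )
    verts, faces, _normals, _values = measure.marching_cubes(
        data, level=level, spacing=tuple(mask.spacing)
    )
    verts = verts + mask.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:  # enforce outward orientation / positive volume
        mesh.invert()
    return mesh


def lumen_isosurface(
    ct: Volume,
    collecting_mask: Volume,
    level: float,
    margin_voxels: tuple = (5, 5, 5),
) -> trimesh.Trimesh:
    """Sub-voxel lumen surface: grayscale marching cubes on the CT.

    The binary mask quantizes the surface to the voxel grid (about half a
    voxel of error, worst at the high-curvature calyceal tips). Contouring
    the CT intensities at the parenchyma/lumen class boundary instead lets
    marching cubes interpolate the crossing inside each voxel, recovering
    the boundary to roughly ``noise_sigma / intensity_step`` voxels. The CT
    is first clamped to background outside a small dilation of
    ``collecting_mask`` so only the extracted component is contoured.
    """
    from .collecting_system import binary_dilate

    ct.require_compatible(collecting_mask, "CT and collecting mask")
    region = binary_dilate(collecting_mask, margin_voxels)
    data = np.where(region.data, ct.data, ct.data.min())
    return extract_isosurface(ct.with_data(data), level=level)


def vertex_normals_angle_weighted(mesh: trimesh.Trimesh) -> np.ndarray:
    """Outward unit vertex normals, face normals averaged with angle weights."""
    normals = trimesh.geometry.weighted_vertex_normals(
        vertex_count=len(mesh.vertices),
        faces=mesh.faces,
        face_normals=mesh.face_normals,
        face_angles=mesh.face_angles,
    )
    lengths = np.linalg.norm(normals, axis=1, keepdims=True)
    lengths[lengths == 0] = 1.0
    return normals / lengths


def dilate_mesh_along_normals(mesh: trimesh.Trimesh, step_mm: float) -> trimesh.Trimesh:
    """Offset every vertex by ``step_mm`` along its unit normal.

    Faces are unchanged, so repeated application with the *original* normals
    is additive; self-intersections at concavities are permitted because the
    registration consumes point samples, not mesh topology.
    """
    if step_mm < 0:
        raise ValueError("step_mm must be >= 0")
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise DegenerateInputError("mesh has no vertices/faces to dilate")
    normals = vertex_normals_angle_weighted(mesh)
    return trimesh.Trimesh(
        vertices=mesh.vertices + step_mm * normals, faces=mesh.faces.copy(),
        process=False,
    )


def surface_sample_points(mesh: trimesh.Trimesh, n: int, seed: int = 0) -> PointCloud:
    """Area-uniform random sample of ``n`` points on the mesh surface.

    Deterministic per seed. Each point carries the normal of the face it
    was drawn from (barycentric interpolation of vertex normals,
    renormalized).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(mesh.faces) == 0:
        raise DegenerateInputError("cannot sample an empty mesh")
    points, face_idx = trimesh.sample.sample_surface(mesh, n, seed=seed)
    vnormals = vertex_normals_angle_weighted(mesh)
    tri_vertices = mesh.vertices[mesh.faces[face_idx]]
    bary = trimesh.triangles.points_to_barycentric(tri_vertices, points)
    interp = np.einsum("nk,nkd->nd", bary, vnormals[mesh.faces[face_idx]])
    lengths = np.linalg.norm(interp, axis=1, keepdims=True)
    degenerate = (lengths[:, 0] < 1e-12)
    if degenerate.any():
        interp[degenerate] = mesh.face_normals[face_idx[degenerate]]
        lengths = np.linalg.norm(interp, axis=1, keepdims=True)
    return PointCloud(np.asarray(points), interp / lengths)
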