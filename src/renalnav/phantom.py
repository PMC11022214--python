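"""Synthetic kidney collecting-system phantoms with full ground truth.

The collecting system is modelled as a rooted tree of capsules (straight
centreline segments with constant radius): one pelvis trunk, a ring of
major calyceal branches, and minor calyces at each major tip. The phantom
emulates a delayed-phase CT, where accumulated contrast makes the lumen
the brightest structure inside a mid-intensity parenchyma, and an SfM-style
reconstruction: lumen-surface points seen from an endoscope trajectory,
expressed in an unknown similarity frame with noise, outliers, and optional
per-branch contraction. Every hidden quantity (masks, transform, trajectory)
is returned so downstream stages can be scored by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .types import CameraTrajectory, PointCloud, SimilarityTransform, Volume

OUTLIER_LABEL = -1

# offsets mixed into the user seed so each stage draws an independent stream
_SEED_TREE = 1
_SEED_NOISE = 2
_SEED_CLOUD = 3
_SEED_TRANSFORM = 4


@dataclass
class PhantomSpec:
    """Parameters of the synthetic phantom.

    Defaults give a desk-scale 128x128x64 grid at 1 mm isotropic spacing
    with background/parenchyma/lumen intensities 0/100/300 HU-like units
    and additive Gaussian noise sigma = 20 — intensity contrast in the
    regime where delayed-phase contrast makes the collecting system the
    brightest class by a wide margin. The clinical-resolution preset
    (512x512x82 at 0.76x0.76x5 mm) is available via :func:`clinical_spec`.
    """

    n_major_branches: int = 3
    n_minor_per_major: int = 2
    branch_length_range: Tuple[float, float] = (14.0, 22.0)
    radius_range: Tuple[float, float] = (1.8, 5.0)
    volume_shape: Tuple[int, int, int] = (128, 128, 64)
    voxel_spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_background: float = 0.0
    intensity_parenchyma: float = 100.0
    intensity_collecting: float = 300.0
    noise_sigma: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_major_branches < 1:
            raise ValueError("n_major_branches must be >= 1")
        if self.n_minor_per_major < 0:
            raise ValueError("n_minor_per_major must be >= 0")
        lo, hi = self.branch_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid branch_length_range {self.branch_length_range}")
        rlo, rhi = self.radius_range
        if not (0 < rlo <= rhi):
            raise ValueError(f"invalid radius_range {self.radius_range}")
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if not (
            self.intensity_collecting
            > self.intensity_parenchyma
            > self.intensity_background
        ):
            raise ValueError(
                "intensities must satisfy collecting > parenchyma > background"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.volume_shape) * np.asarray(self.voxel_spacing)


def clinical_spec(**overrides) -> PhantomSpec:
    """Preset matching a clinical delayed-phase CT grid (512x512x82,
    0.76x0.76x5 mm). Branch geometry scales with the larger field of view."""
    params = dict(
        volume_shape=(512, 512, 82),
        voxel_spacing=(0.76, 0.76, 5.0),
        branch_length_range=(25.0, 40.0),
        radius_range=(2.5, 8.0),
    )
    params.update(overrides)
    return PhantomSpec(**params)


@dataclass
class TreeSkeleton:
    """Rooted tree of straight centreline segments with per-edge radius.

    ``nodes`` are world-mm points; ``edges`` are (parent, child) node-index
    pairs; each edge is one branch segment carrying its own ``branch_id``.
    """

    nodes: np.ndarray
    edges: np.ndarray
    radius_per_edge: np.ndarray
    branch_id_per_edge: np.ndarray

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.radius_per_edge = np.asarray(self.radius_per_edge, dtype=float)
        self.branch_id_per_edge = np.asarray(self.branch_id_per_edge, dtype=int)
        self.validate()

    def validate(self) -> None:
        n_nodes, n_edges = len(self.nodes), len(self.edges)
        if n_edges != n_nodes - 1:
            raise ValueError("a tree on n nodes must have n-1 edges")
        if np.any(self.radius_per_edge <= 0):
            raise ValueError("all radii must be positive")
        children = self.edges[:, 1]
        if len(np.unique(children)) != n_edges or 0 in children:
            raise ValueError("each non-root node must have exactly one parent")
        # connectivity: every node reachable from root 0
        reached = {0}
        frontier = [0]
        adj: Dict[int, list] = {}
        for p, c in self.edges:
            adj.setdefault(int(p), []).append(int(c))
        while frontier:
            node = frontier.pop()
            for child in adj.get(node, []):
                if child not in reached:
                    reached.add(child)
                    frontier.append(child)
        if len(reached) != n_nodes:
            raise ValueError("skeleton is not connected from the root")

    @property
    def n_branches(self) -> int:
        return len(self.edges)

    def segment(self, edge_index: int) -> Tuple[np.ndarray, np.ndarray]:
        p, c = self.edges[edge_index]
        return self.nodes[p], self.nodes[c]

    def edge_order_dfs(self) -> np.ndarray:
        """Edge indices in depth-first order from the root (deterministic:
        children visited in edge-list order)."""
        by_parent: Dict[int, list] = {}
        for i, (p, _c) in enumerate(self.edges):
            by_parent.setdefault(int(p), []).append(i)
        order = []
        stack = list(reversed(by_parent.get(0, [])))
        while stack:
            ei = stack.pop()
            order.append(ei)
            child = int(self.edges[ei, 1])
            stack.extend(reversed(by_parent.get(child, [])))
        return np.asarray(order, dtype=int)

    def ancestors_of_edge(self, edge_index: int) -> list:
        """Edge indices on the path root -> this edge, inclusive."""
        parent_edge = {int(c): i for i, (_p, c) in enumerate(self.edges)}
        path = [edge_index]
        node = int(self.edges[edge_index, 0])
        while node != 0:
            ei = parent_edge[node]
            path.append(ei)
            node = int(self.edges[ei, 0])
        return path[::-1]


@dataclass
class GroundTruth:
    """Everything hidden from the pipeline but known to the simulator."""

    tree: TreeSkeleton
    collecting_mask: Volume
    kidney_mask: Volume
    true_transform: Optional[SimilarityTransform] = None
    true_trajectory_ct: Optional[CameraTrajectory] = None
    contraction_factors: Optional[np.ndarray] = None


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _flatten_z(direction: np.ndarray, factor: float = 0.5) -> np.ndarray:
    """Compress the z-component so trees fit thin axial fields of view."""
    d = direction.copy()
    d[2] *= factor
    return _unit(d)


def build_tree_skeleton(spec: PhantomSpec) -> TreeSkeleton:
    """Construct the branched lumen skeleton: pelvis trunk -> major calyces
    -> minor calyces. Deterministic for a given spec (seeded RNG).

    Branch radii taper from ``radius_range[1]`` at the pelvis to
    ``radius_range[0]`` at the minor calyces.
    """
    spec.validate()
    rng = np.random.default_rng((spec.seed, _SEED_TREE))
    extent = spec.extent_mm

    root = np.array([0.5 * extent[0], 0.28 * extent[1], 0.5 * extent[2]])
    trunk_dir = _unit(np.array([0.0, 1.0, 0.0]) + rng.normal(0, 0.05, 3))
    trunk_len = float(np.mean(spec.branch_length_range))
    r_min, r_max = spec.radius_range
    r_major = float(np.sqrt(r_min * r_max))

    nodes = [root, root + trunk_len * trunk_dir]
    edges = [(0, 1)]
    radii = [r_max]

    lo, hi = spec.branch_length_range
    azimuths = (
        np.linspace(0, 2 * np.pi, spec.n_major_branches, endpoint=False)
        + rng.uniform(-0.25, 0.25, spec.n_major_branches)
    )
    # orthonormal frame around the trunk direction
    e1 = _unit(np.cross(trunk_dir, [0.0, 0.0, 1.0]))
    e2 = np.cross(trunk_dir, e1)

    for j in range(spec.n_major_branches):
        polar = rng.uniform(np.deg2rad(32), np.deg2rad(58))
        d = (
            np.cos(polar) * trunk_dir
            + np.sin(polar) * (np.cos(azimuths[j]) * e1 + np.sin(azimuths[j]) * e2)
        )
        d = _flatten_z(d)
        length = rng.uniform(lo, hi)
        tip = nodes[1] + length * d
        major_node = len(nodes)
        nodes.append(tip)
        edges.append((1, major_node))
        radii.append(r_major)

        # frame around the major branch
        f1 = _unit(np.cross(d, [0.0, 0.0, 1.0] if abs(d[2]) < 0.9 else [1.0, 0.0, 0.0]))
        f2 = np.cross(d, f1)
        minor_az = (
            np.linspace(0, 2 * np.pi, max(spec.n_minor_per_major, 1), endpoint=False)
            + rng.uniform(0, 2 * np.pi)
        )
        for k in range(spec.n_minor_per_major):
            polar_m = rng.uniform(np.deg2rad(20), np.deg2rad(45))
            dm = (
                np.cos(polar_m) * d
                + np.sin(polar_m) * (np.cos(minor_az[k]) * f1 + np.sin(minor_az[k]) * f2)
            )
            dm = _flatten_z(dm)
            length_m = 0.6 * rng.uniform(lo, hi)
            nodes.append(tip + length_m * dm)
            edges.append((major_node, len(nodes) - 1))
            radii.append(r_min)

    return TreeSkeleton(
        nodes=np.asarray(nodes),
        edges=np.asarray(edges),
        radius_per_edge=np.asarray(radii),
        branch_id_per_edge=np.arange(len(edges)),
    )


def _segment_distance_field(
    shape: Sequence[int],
    spacing: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    radius: float,
) -> Tuple[tuple, np.ndarray]:
    """Boolean capsule rasterization restricted to the segment's bounding
    box. Returns (slices, mask_within_box)."""
    lo = np.minimum(a, b) - radius
    hi = np.maximum(a, b) + radius
    i0 = np.maximum(np.floor(lo / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / spacing).astype(int) + 1, np.asarray(shape))
    slices = tuple(slice(int(i0[d]), int(i1[d])) for d in range(3))
    grids = np.meshgrid(
        *[(np.arange(i0[d], i1[d]) * spacing[d]) for d in range(3)], indexing="ij"
    )
    pts = np.stack([g.ravel() for g in grids], axis=1)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        dist = np.linalg.norm(pts - a, axis=1)
    else:
        t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
        dist = np.linalg.norm(pts - (a + t[:, None] * ab), axis=1)
    return slices, (dist <= radius).reshape([int(i1[d] - i0[d]) for d in range(3)])


def rasterize_phantom_ct(
    tree: TreeSkeleton, spec: PhantomSpec
) -> Tuple[Volume, Volume, Volume]:
    """Rasterize the tree into a noisy CT volume plus noise-free masks.

    Returns ``(ct, collecting_mask, kidney_mask)``. Lumen voxels (within
    radius of a centreline) get ``intensity_collecting``; an enclosing
    parenchyma ellipsoid gets ``intensity_parenchyma``; the rest is
    background. Gaussian noise (sigma = ``spec.noise_sigma``) is added to
    the CT only; the masks stay clean.
    """
    spec.validate()
    shape = tuple(spec.volume_shape)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    extent = spec.extent_mm

    for i, node in enumerate(tree.nodes):
        margin = float(np.max(tree.radius_per_edge))
        if np.any(node < margin) or np.any(node > extent - margin):
            raise ValueError(
                f"tree node {i} at {node} exceeds volume bounds {extent} "
                f"(margin {margin} mm)"
            )

    collecting = np.zeros(shape, dtype=bool)
    for ei in range(tree.n_branches):
        a, b = tree.segment(ei)
        sl, box = _segment_distance_field(shape, spacing, a, b, tree.radius_per_edge[ei])
        collecting[sl] |= box

    # parenchyma: ellipsoid hugging the tree bounding box with a 10 mm pad
    bb_lo, bb_hi = tree.nodes.min(axis=0), tree.nodes.max(axis=0)
    centre = 0.5 * (bb_lo + bb_hi)
    semi = 0.5 * (bb_hi - bb_lo) + 10.0 + np.max(tree.radius_per_edge)
    grids = np.meshgrid(
        *[(np.arange(shape[d]) * spacing[d]) for d in range(3)], indexing="ij"
    )
    q = sum(((grids[d] - centre[d]) / semi[d]) ** 2 for d in range(3))
    kidney = (q <= 1.0) | collecting

    ct = np.full(shape, spec.intensity_background, dtype=float)
    ct[kidney] = spec.intensity_parenchyma
    ct[collecting] = spec.intensity_collecting
    if spec.noise_sigma > 0:
        rng = np.random.default_rng((spec.seed, _SEED_NOISE))
        ct = ct + rng.normal(0.0, spec.noise_sigma, shape)

    vol = Volume(ct, spacing)
    return vol, vol.with_data(collecting), vol.with_data(kidney)


def _quaternion_from_view(direction: np.ndarray) -> np.ndarray:
    """World-from-camera quaternion (w, x, y, z) whose camera +z axis points
    along ``direction`` (minimal rotation from +z)."""
    z = np.array([0.0, 0.0, 1.0])
    d = _unit(direction)
    axis = np.cross(z, d)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if d[2] > 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        return np.array([0.0, 1.0, 0.0, 0.0])  # 180 deg about x
    angle = np.arctan2(s, float(z @ d))
    rot = Rotation.from_rotvec(angle * axis / s)
    x, y, zq, w = rot.as_quat()
    return np.array([w, x, y, zq])


def simulate_endoscope_trajectory(
    tree: TreeSkeleton,
    frames_per_branch: int,
    branch_ids: Optional[Iterable[int]] = None,
    include_return: bool = False,
) -> CameraTrajectory:
    """Thread a camera along the centrelines in depth-first order.

    Emits ``frames_per_branch`` poses per visited branch segment on the
    forward pass (by default the retreat back toward the root revisits the
    same centreline without adding frames, so the trajectory length is
    exactly ``frames_per_branch`` per visited segment). Poses sit on the
    centreline at interior fractions, so every position is strictly inside
    the lumen; orientation looks along the local path tangent. When
    ``branch_ids`` is given, only those branches (plus the segments leading
    to them) are visited. ``include_return=True`` additionally emits poses
    on the withdrawal pass looking back toward the root — the inspect-on-
    entry-and-withdrawal pattern of a thorough endoscopy, which also makes
    the region behind the entry poses visible to the camera.
    """
    if frames_per_branch < 1:
        raise ValueError("frames_per_branch must be >= 1")
    keep = None
    if branch_ids is not None:
        wanted = set(int(b) for b in branch_ids)
        keep = set()
        for ei in range(tree.n_branches):
            if int(tree.branch_id_per_edge[ei]) in wanted:
                keep.update(tree.ancestors_of_edge(ei))

    by_parent: Dict[int, list] = {}
    for i, (p, _c) in enumerate(tree.edges):
        by_parent.setdefault(int(p), []).append(i)

    positions, quats = [], []
    fracs = (np.arange(frames_per_branch) + 1.0) / (frames_per_branch + 1.0)

    def emit(ei: int, backward: bool) -> None:
        a, b = tree.segment(ei)
        tangent = _unit(b - a)
        fr = fracs[::-1] if backward else fracs
        view = -tangent if backward else tangent
        for f in fr:
            positions.append(a + f * (b - a))
            quats.append(_quaternion_from_view(view))

    def walk(node: int) -> None:
        for ei in by_parent.get(node, []):
            if keep is not None and ei not in keep:
                continue
            emit(ei, backward=False)
            walk(int(tree.edges[ei, 1]))
            if include_return:
                emit(ei, backward=True)

    walk(0)
    return CameraTrajectory(
        frame_ids=np.arange(len(positions)),
        positions=np.asarray(positions).reshape(-1, 3),
        quaternions=np.asarray(quats).reshape(-1, 4),
    )


def random_similarity_transform(
    seed: int, scale: float = 1.0, translation_mm: float = 30.0
) -> SimilarityTransform:
    """A reproducible random similarity transform: uniform random rotation,
    translation uniform in a cube of half-width ``translation_mm``."""
    rng = np.random.default_rng((seed, _SEED_TRANSFORM))
    rot = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-translation_mm, translation_mm, 3)
    return SimilarityTransform(scale, rot, t)


def visible_from_trajectory(
    points: np.ndarray,
    trajectory: CameraTrajectory,
    max_view_distance_mm: float = 15.0,
    view_half_angle_deg: float = 70.0,
) -> np.ndarray:
    """Boolean visibility of each point under the endoscope viewing model:
    a point is visible if it lies within ``max_view_distance_mm`` of some
    pose and inside that pose's viewing cone. No occlusion is modelled."""
    points = np.asarray(points, dtype=float)
    pose_tree = cKDTree(trajectory.positions)
    views = trajectory.view_directions()
    cos_half = np.cos(np.deg2rad(view_half_angle_deg))
    neighbor_lists = pose_tree.query_ball_point(points, r=max_view_distance_mm)
    visible = np.zeros(len(points), dtype=bool)
    for i, poses in enumerate(neighbor_lists):
        for j in poses:
            rel = points[i] - trajectory.positions[j]
            norm = np.linalg.norm(rel)
            if norm < 1e-9 or rel @ views[j] >= cos_half * norm:
                visible[i] = True
                break
    return visible


def _sample_lumen_surface(
    tree: TreeSkeleton, n_points: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Area-weighted samples on the capsule side surfaces, excluding points
    swallowed by another branch's lumen at junctions. Returns (points,
    branch labels)."""
    segs = [tree.segment(ei) for ei in range(tree.n_branches)]
    lengths = np.array([np.linalg.norm(b - a) for a, b in segs])
    side_areas = 2 * np.pi * tree.radius_per_edge * lengths
    cap_areas = 2 * np.pi * tree.radius_per_edge**2  # hemisphere per end
    total = (side_areas + 2 * cap_areas).sum()

    pts_all, labels_all = [], []
    for ei, (a, b) in enumerate(segs):
        r = tree.radius_per_edge[ei]
        axis = _unit(b - a)
        helper = [0.0, 0.0, 1.0] if abs(axis[2]) < 0.9 else [1.0, 0.0, 0.0]
        e1 = _unit(np.cross(axis, helper))
        e2 = np.cross(axis, e1)

        count = max(int(n_points * side_areas[ei] / total), 8)
        t = rng.uniform(0.04, 0.96, count)
        phi = rng.uniform(0, 2 * np.pi, count)
        pts = (
            a
            + t[:, None] * (b - a)
            + r * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        )
        pts_all.append(pts)
        labels_all.append(np.full(count, tree.branch_id_per_edge[ei], dtype=int))

        # hemispherical end caps (blind calyceal ends, pelvis floor); caps
        # swallowed by a neighbouring branch are removed by the filter below
        n_cap = max(int(n_points * cap_areas[ei] / total), 4)
        for centre, outward in ((a, -axis), (b, axis)):
            w = rng.normal(size=(n_cap, 3))
            w /= np.linalg.norm(w, axis=1, keepdims=True)
            flip = (w @ outward) < 0
            w[flip] -= 2 * (w[flip] @ outward)[:, None] * outward
            pts_all.append(centre + r * w)
            labels_all.append(
                np.full(n_cap, tree.branch_id_per_edge[ei], dtype=int)
            )
    pts = np.concatenate(pts_all)
    labels = np.concatenate(labels_all)

    # drop points lying inside a *different* branch's lumen (junction overlap)
    inside_other = np.zeros(len(pts), dtype=bool)
    for ei, (a, b) in enumerate(segs):
        ab = b - a
        denom = float(ab @ ab)
        tproj = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
        dist = np.linalg.norm(pts - (a + tproj[:, None] * ab), axis=1)
        other = labels != tree.branch_id_per_edge[ei]
        inside_other |= other & (dist < tree.radius_per_edge[ei] - 1e-9)
    return pts[~inside_other], labels[~inside_other]


def synthesize_reconstruction_cloud(
    gt: GroundTruth,
    trajectory: CameraTrajectory,
    noise_sigma_mm: float = 0.0,
    outlier_fraction: float = 0.0,
    transform: Optional[SimilarityTransform] = None,
    contraction: Optional[Dict[int, float]] = None,
    n_surface_points: int = 20000,
    max_view_distance_mm: float = 15.0,
    view_half_angle_deg: float = 70.0,
    seed: int = 0,
) -> Tuple[PointCloud, CameraTrajectory]:
    """Emulate SfM output: visible lumen-surface points in an unknown frame.

    Steps: (1) sample the lumen surface area-uniformly; (2) keep points
    visible from the trajectory (within ``max_view_distance_mm`` of some
    pose and inside its viewing cone); (3) contract each branch's points
    radially toward its centreline axis by its contraction factor;
    (4) map into the reconstruction frame with the INVERSE of ``transform``
    (so that registering cloud -> CT must recover ``transform``); (5) add
    isotropic Gaussian noise; (6) append uniform outliers inside the 20 %%
    inflated bounding box (labelled ``OUTLIER_LABEL``).

    Returns the cloud plus the trajectory expressed in the reconstruction
    frame.
    """
    if not (0 <= outlier_fraction < 1):
        raise ValueError("outlier_fraction must be in [0, 1)")
    transform = transform if transform is not None else SimilarityTransform.identity()
    rng = np.random.default_rng((seed, _SEED_CLOUD))
    tree = gt.tree

    pts, labels = _sample_lumen_surface(tree, n_surface_points, rng)

    visible = visible_from_trajectory(
        pts, trajectory, max_view_distance_mm, view_half_angle_deg
    )
    pts, labels = pts[visible], labels[visible]
    if len(pts) == 0:
        raise ValueError("no lumen surface points visible from the trajectory")

    if contraction:
        for branch_id, factor in contraction.items():
            sel = labels == branch_id
            if not np.any(sel):
                continue
            ei = int(np.nonzero(tree.branch_id_per_edge == branch_id)[0][0])
            a, b = tree.segment(ei)
            ab = b - a
            tproj = (pts[sel] - a) @ ab / float(ab @ ab)
            foot = a + tproj[:, None] * ab
            pts[sel] = foot + factor * (pts[sel] - foot)

    inv = transform.inverse()
    recon_pts = inv.apply(pts)
    if noise_sigma_mm > 0:
        recon_pts = recon_pts + rng.normal(0.0, noise_sigma_mm, recon_pts.shape)

    n_out = int(round(outlier_fraction * len(recon_pts)))
    if n_out:
        lo, hi = recon_pts.min(axis=0), recon_pts.max(axis=0)
        pad = 0.2 * (hi - lo)
        outliers = rng.uniform(lo - pad, hi + pad, (n_out, 3))
        recon_pts = np.vstack([recon_pts, outliers])
        labels = np.concatenate([labels, np.full(n_out, OUTLIER_LABEL)])

    recon_traj = CameraTrajectory(
        frame_ids=trajectory.frame_ids.copy(),
        positions=inv.apply(trajectory.positions),
        quaternions=_rotate_quaternions(trajectory.quaternions, inv.rotation),
    )
    return PointCloud(recon_pts, labels=labels), recon_traj


def _rotate_quaternions(quats_wxyz: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    rot = Rotation.from_matrix(rotation)
    q = Rotation.from_quat(np.asarray(quats_wxyz)[:, [1, 2, 3, 0]])
    out = (rot * q).as_quat()  # (x, y, z, w)
    out = out[:, [3, 0, 1, 2]]
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    return out / norms


def make_phantom(
    spec: PhantomSpec,
    frames_per_branch: int = 6,
    transform: Optional[SimilarityTransform] = None,
    noise_sigma_mm: float = 0.0,
    outlier_fraction: float = 0.0,
    contraction: Optional[Dict[int, float]] = None,
    n_surface_points: int = 20000,
    branch_ids: Optional[Iterable[int]] = None,
    include_return: bool = False,
) -> Tuple[Volume, GroundTruth, PointCloud, CameraTrajectory]:
    """Convenience wrapper running the full simulation chain.

    Returns ``(ct, ground_truth, reconstruction_cloud, recon_trajectory)``.
    """
    tree = build_tree_skeleton(spec)
    ct, collecting_mask, kidney_mask = rasterize_phantom_ct(tree, spec)
    trajectory = simulate_endoscope_trajectory(
        tree, frames_per_branch, branch_ids, include_return
    )
    transform = transform if transform is not None else SimilarityTransform.identity()
    gt = GroundTruth(
        tree=tree,
        collecting_mask=collecting_mask,
        kidney_mask=kidney_mask,
        true_transform=transform,
        true_trajectory_ct=trajectory,
    )
    cloud, recon_traj = synthesize_reconstruction_cloud(
        gt,
        trajectory,
        noise_sigma_mm=noise_sigma_mm,
        outlier_fraction=outlier_fraction,
        transform=transform,
        contraction=contraction,
        n_surface_points=n_surface_points,
        seed=spec.seed,
    )
    if contraction:
        factors = np.ones(tree.n_branches)
        for b, f in contraction.items():
            factors[tree.branch_id_per_edge == b] = f
        gt.contraction_factors = factors
    return ct, gt, cloud, recon_traj
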