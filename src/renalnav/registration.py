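"""Reconstruction-to-CT point-cloud registration.

The SfM reconstruction lives in an arbitrary similarity frame (unknown
scale, rotation, translation), so alignment proceeds in stages: radial
outlier filtering, voxel-grid downsampling, normal estimation, FPFH
descriptors, global alignment (feature-matched RANSAC, or a
correspondence-seeded Umeyama fit when manual picks are available), and
point-to-point ICP refinement with the scale frozen. Quality is reported
as inlier RMSE and fitness (inlier share), mirroring how registration
toolkits summarise an alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, minimum_spanning_tree
from scipy.spatial import cKDTree

from .types import (
    DegenerateInputError,
    PointCloud,
    RegistrationResult,
    SimilarityTransform,
)

# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def voxel_downsample(cloud: PointCloud, voxel_mm: float) -> PointCloud:
    """One point per occupied voxel of an axis-aligned grid: the centroid of
    the voxel's members. Output ordered by lexicographic voxel index.

    Labels (when present) are carried over from the member with the lowest
    original index, keeping branch identity through the downsampling.
    """
    if voxel_mm <= 0:
        raise ValueError("voxel_mm must be positive")
    if len(cloud) == 0:
        return PointCloud(np.empty((0, 3)))
    idx = np.floor(cloud.points / voxel_mm).astype(np.int64)
    uniq, inverse = np.unique(idx, axis=0, return_inverse=True)
    n_vox = len(uniq)
    sums = np.zeros((n_vox, 3))
    np.add.at(sums, inverse, cloud.points)
    counts = np.bincount(inverse, minlength=n_vox).astype(float)
    centroids = sums / counts[:, None]
    labels = None
    if cloud.labels is not None:
        first = np.full(n_vox, len(cloud), dtype=np.int64)
        np.minimum.at(first, inverse, np.arange(len(cloud)))
        labels = cloud.labels[first]
    return PointCloud(centroids, labels=labels)


def radial_neighbor_filter(cloud: PointCloud, radius_mm: float) -> PointCloud:
    """Keep only points that have at least one *other* point within
    ``radius_mm``; isolated points (typical of spurious SfM matches on
    debris) are discarded. Point order is preserved."""
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if len(cloud) < 2:
        return cloud.select(np.zeros(len(cloud), dtype=bool))
    tree = cKDTree(cloud.points)
    dist, _ = tree.query(cloud.points, k=2)
    return cloud.select(dist[:, 1] <= radius_mm)


def estimate_normals(
    cloud: PointCloud, radius_mm: float, k_max: int = 30
) -> PointCloud:
    """Per-point normals from local PCA, with consistent orientation.

    Each normal is the smallest-eigenvalue eigenvector of the covariance of
    the neighbours within ``radius_mm`` (capped at the ``k_max`` nearest).
    Points with fewer than 3 neighbourhood members get a NaN (invalid)
    normal. Signs are made locally consistent by propagating along a
    minimum spanning tree of the neighbour graph, seeded outward from the
    cloud centroid — adequate for the closed, outward-oriented surfaces
    registered here.
    """
    pts = cloud.points
    n = len(pts)
    if n < 3:
        normals = np.full((n, 3), np.nan)
        return PointCloud(pts.copy(), normals if n else None, cloud.labels)

    tree = cKDTree(pts)
    k = min(k_max, n)
    dist, idx = tree.query(pts, k=k)
    valid = dist <= radius_mm  # self included at distance 0

    counts = valid.sum(axis=1)
    neighbor_pts = pts[idx]  # (n, k, 3)
    w = valid.astype(float)[:, :, None]
    means = (neighbor_pts * w).sum(axis=1) / np.maximum(counts, 1)[:, None]
    diffs = (neighbor_pts - means[:, None, :]) * w
    cov = np.einsum("nkd,nke->nde", diffs, diffs)

    normals = np.full((n, 3), np.nan)
    ok = counts >= 3
    if ok.any():
        _vals, vecs = np.linalg.eigh(cov[ok])
        normals[ok] = vecs[:, :, 0]  # smallest eigenvalue first

    # orientation: propagate sign along an MST of the kNN graph
    ok_idx = np.nonzero(ok)[0]
    if len(ok_idx) > 1:
        sub = pts[ok_idx]
        sub_tree = cKDTree(sub)
        kk = min(8, len(sub))
        d, j = sub_tree.query(sub, k=kk)
        rows = np.repeat(np.arange(len(sub)), kk - 1)
        cols = j[:, 1:].ravel()
        vals = d[:, 1:].ravel() + 1e-12
        graph = coo_matrix((vals, (rows, cols)), shape=(len(sub), len(sub)))
        mst = minimum_spanning_tree(graph)
        mst = mst + mst.T
        order, pred = breadth_first_order(mst, 0, directed=False)
        centroid = sub.mean(axis=0)
        seed = ok_idx[order[0]]
        if normals[seed] @ (pts[seed] - centroid) < 0:
            normals[seed] = -normals[seed]
        for node in order[1:]:
            parent = pred[node]
            gi, gp = ok_idx[node], ok_idx[parent]
            if normals[gi] @ normals[gp] < 0:
                normals[gi] = -normals[gi]
    elif len(ok_idx) == 1:
        pass  # single valid normal: sign arbitrary

    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        normals = normals / norms
    return PointCloud(pts.copy(), normals, cloud.labels)


# ---------------------------------------------------------------------------
# FPFH descriptors
# ---------------------------------------------------------------------------

FPFH_BINS = 11  # per angular feature; 3 features -> 33-dim descriptor


def _pair_features(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Darboux-frame angle triple (alpha, phi, theta) per point pair.

    For each pair the source point is the one whose normal is better
    aligned with the connecting line, which makes the triple a symmetric
    property of the unordered pair. Vectorized over rows.
    """
    d = p2 - p1
    dist = np.linalg.norm(d, axis=1)
    dist_safe = np.where(dist > 0, dist, 1.0)
    dhat = d / dist_safe[:, None]

    dot1 = np.einsum("ij,ij->i", n1, dhat)
    dot2 = np.einsum("ij,ij->i", n2, dhat)
    swap = np.abs(dot1) < np.abs(dot2)

    ns = np.where(swap[:, None], n2, n1)
    nt = np.where(swap[:, None], n1, n2)
    dhat = np.where(swap[:, None], -dhat, dhat)

    u = ns
    v = np.cross(dhat, u)
    vnorm = np.linalg.norm(v, axis=1, keepdims=True)
    vnorm[vnorm == 0] = 1.0
    v = v / vnorm
    w = np.cross(u, v)

    alpha = np.einsum("ij,ij->i", v, nt)
    phi = np.einsum("ij,ij->i", u, dhat)
    theta = np.arctan2(np.einsum("ij,ij->i", w, nt), np.einsum("ij,ij->i", u, nt))
    return alpha, phi, theta


def _bin_triple(alpha, phi, theta) -> np.ndarray:
    """Map the angle triples to flat indices in a 3 x 11 histogram layout."""
    ia = np.clip(((alpha + 1.0) / 2.0 * FPFH_BINS).astype(int), 0, FPFH_BINS - 1)
    ip = np.clip(((phi + 1.0) / 2.0 * FPFH_BINS).astype(int), 0, FPFH_BINS - 1)
    it = np.clip(
        ((theta + np.pi) / (2 * np.pi) * FPFH_BINS).astype(int), 0, FPFH_BINS - 1
    )
    return ia, ip + FPFH_BINS, it + 2 * FPFH_BINS


def compute_fpfh(cloud: PointCloud, radius_mm: float) -> np.ndarray:
    """Fast Point Feature Histograms: a 33-dim descriptor per point.

    Two passes. First, each point's simplified histogram (SPFH) bins the
    (alpha, phi, theta) Darboux angles against every neighbour within
    ``radius_mm``. Second, the final descriptor re-weights neighbours'
    SPFHs by inverse distance:

        FPFH(p) = SPFH(p) + (1/k) * sum_q SPFH(q) / ||p - q||

    and each 11-bin sub-histogram is normalized to sum to 100. Points with
    an invalid normal or no neighbour get an all-zero row.
    """
    if cloud.normals is None:
        raise ValueError("cloud must carry normals (run estimate_normals first)")
    n = len(cloud)
    features = np.zeros((n, 3 * FPFH_BINS))
    valid = cloud.valid_normal_mask
    vidx = np.nonzero(valid)[0]
    if len(vidx) < 2:
        return features

    pts = cloud.points[vidx]
    nrm = cloud.normals[vidx]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius_mm, output_type="ndarray")
    if len(pairs) == 0:
        return features

    i, j = pairs[:, 0], pairs[:, 1]
    alpha, phi, theta = _pair_features(pts[i], nrm[i], pts[j], nrm[j])
    ia, ip, it = _bin_triple(alpha, phi, theta)

    m = len(pts)
    spfh = np.zeros((m, 3 * FPFH_BINS))
    for bins in (ia, ip, it):
        np.add.at(spfh, (i, bins), 1.0)
        np.add.at(spfh, (j, bins), 1.0)

    k_count = np.bincount(i, minlength=m) + np.bincount(j, minlength=m)
    dist = np.linalg.norm(pts[i] - pts[j], axis=1)
    wgt = 1.0 / np.maximum(dist, 1e-12)

    weighted = np.zeros((m, 3 * FPFH_BINS))
    np.add.at(weighted, i, spfh[j] * wgt[:, None])
    np.add.at(weighted, j, spfh[i] * wgt[:, None])

    has_nb = k_count > 0
    fpfh = spfh.copy()
    fpfh[has_nb] += weighted[has_nb] / k_count[has_nb, None]

    for b in range(3):
        block = fpfh[:, b * FPFH_BINS : (b + 1) * FPFH_BINS]
        sums = block.sum(axis=1, keepdims=True)
        nz = sums[:, 0] > 0
        block[nz] = block[nz] / sums[nz] * 100.0
    features[vidx] = fpfh
    return features


# ---------------------------------------------------------------------------
# Scale and closed-form similarity
# ---------------------------------------------------------------------------


def estimate_scale_from_extents(source: PointCloud, target: PointCloud) -> float:
    """Scale guess from robust principal-axis extents (target / source).

    Each cloud's extent is the 5th-to-95th-percentile span of projections
    onto its own first principal axis. The 5/95 trim keeps the estimate
    insensitive to ~5 %% of bounding-box outliers, whose mass sits in the
    projection tails and would dominate a tighter percentile pair.
    """

    def robust_extent(cloud: PointCloud) -> float:
        if len(cloud) < 2:
            raise DegenerateInputError("need >= 2 points to measure an extent")
        pts = cloud.points - cloud.points.mean(axis=0)
        _vals, vecs = np.linalg.eigh(pts.T @ pts)
        proj = pts @ vecs[:, -1]
        lo, hi = np.percentile(proj, [5, 95])
        return float(hi - lo)

    ext_s, ext_t = robust_extent(source), robust_extent(target)
    if ext_s <= 1e-12 or ext_t <= 1e-12:
        raise DegenerateInputError("zero-extent cloud: cannot estimate scale")
    return ext_t / ext_s


def umeyama_similarity(
    source_pts: np.ndarray, target_pts: np.ndarray, with_scale: bool = True
) -> SimilarityTransform:
    """Closed-form least-squares similarity (or rigid) alignment of paired
    points: minimizes sum ||s R x_i + t - y_i||^2 via SVD of the
    cross-covariance, with the determinant correction that excludes
    reflections."""
    x = np.asarray(source_pts, dtype=float)
    y = np.asarray(target_pts, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("source and target must both be K x 3")
    k = len(x)
    if k < 3:
        raise DegenerateInputError("need at least 3 correspondences")

    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    cov = yc.T @ xc / k
    u, s, vt = np.linalg.svd(cov)
    if np.linalg.matrix_rank(cov, tol=1e-10) < 2 or s[1] < 1e-12 * max(s[0], 1.0):
        raise DegenerateInputError("correspondences are collinear/degenerate")
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    rot = u @ diag @ vt
    if with_scale:
        var_x = (xc**2).sum() / k
        scale = float(np.trace(np.diag(s) @ diag) / var_x)
    else:
        scale = 1.0
    trans = my - scale * rot @ mx
    return SimilarityTransform(scale, rot, trans)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def registration_metrics(
    source: PointCloud,
    target: PointCloud,
    transform: SimilarityTransform,
    max_corr_mm: float,
) -> RegistrationResult:
    """Inlier RMSE and fitness of ``transform`` applied to ``source``.

    A source point is an inlier iff its nearest target point after
    transformation lies within ``max_corr_mm``. With zero inliers the RMSE
    is reported as 0.0 (flagged via ``zero_inliers``)."""
    moved = transform.apply(source.points)
    tree = cKDTree(target.points)
    dist, _ = tree.query(moved)
    inlier = dist <= max_corr_mm
    count = int(inlier.sum())
    rmse = float(np.sqrt(np.mean(dist[inlier] ** 2))) if count else 0.0
    return RegistrationResult(
        transform=transform,
        inlier_rmse=rmse,
        inlier_count=count,
        total_source_points=len(source),
        correspondence_threshold=max_corr_mm,
    )


# ---------------------------------------------------------------------------
# Global registration (RANSAC on FPFH matches)
# ---------------------------------------------------------------------------


@dataclass
class RansacParams:
    distance_threshold_mm: float = 1.5
    n_sample: int = 3
    max_iters: int = 100_000
    edge_length_ratio: float = 0.9
    confidence: float = 0.9999
    eval_subsample: int = 1000


def _nearest_feature_match(
    source_fpfh: np.ndarray, target_fpfh: np.ndarray, target_valid: np.ndarray
) -> np.ndarray:
    """Index of the nearest valid target feature per source row, with exact
    ties resolved to the smallest target index."""
    tidx = np.nonzero(target_valid)[0]
    tree = cKDTree(target_fpfh[tidx])
    k = min(2, len(tidx))
    dist, j = tree.query(source_fpfh, k=k)
    if k == 1:
        return tidx[np.atleast_1d(j)]
    j = np.atleast_2d(j)
    dist = np.atleast_2d(dist)
    best = tidx[j[:, 0]]
    tie = np.isclose(dist[:, 0], dist[:, 1])
    alt = tidx[j[:, 1]]
    best[tie] = np.minimum(best[tie], alt[tie])
    return best


def feature_correspondences(
    source_fpfh: np.ndarray, target_fpfh: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FPFH correspondence candidates for global registration.

    Returns ``(source_idx, target_idx, mutual)`` where each source point
    with a valid descriptor is paired with its nearest target descriptor
    and ``mutual`` flags reciprocal nearest-neighbour pairs. Mutual pairs
    are far more precise on self-similar tubular surfaces (a point on a
    featureless tube wall matches many places; junctions and tips match
    uniquely in both directions), so RANSAC samples from them when enough
    exist.
    """
    src_valid = np.nonzero(source_fpfh.sum(axis=1) > 0)[0]
    tgt_valid = target_fpfh.sum(axis=1) > 0
    if len(src_valid) == 0 or not tgt_valid.any():
        return np.empty(0, int), np.empty(0, int), np.empty(0, bool)
    match_st = _nearest_feature_match(source_fpfh[src_valid], target_fpfh, tgt_valid)
    tidx = np.nonzero(tgt_valid)[0]
    back = _nearest_feature_match(
        target_fpfh[tidx], source_fpfh, np.isin(np.arange(len(source_fpfh)), src_valid)
    )
    # mutual: the target's preferred source is this source point
    t_to_back = dict(zip(tidx, back))
    mutual = np.array(
        [t_to_back.get(t, -1) == s for s, t in zip(src_valid, match_st)], dtype=bool
    )
    return src_valid, match_st, mutual


def ransac_global_register(
    source: PointCloud,
    target: PointCloud,
    source_fpfh: np.ndarray,
    target_fpfh: np.ndarray,
    params: Optional[RansacParams] = None,
    seed: int = 0,
) -> RegistrationResult:
    """Feature-matched RANSAC global rigid alignment.

    Each iteration draws ``n_sample`` source points, pairs them with their
    nearest-FPFH target points, prunes by pairwise edge-length compatibility
    (all length ratios >= ``edge_length_ratio``), fits a rigid transform,
    and checks that the sampled correspondences themselves land within the
    distance threshold. Surviving candidates are scored by inlier count
    (ties by RMSE) on a fixed evaluation subsample; iteration stops early
    once the standard (1 - fitness^n) confidence bound is met.
    Deterministic per seed. The returned metrics are computed on the full
    clouds at the distance threshold.
    """
    params = params or RansacParams()
    rng = np.random.default_rng(seed)
    failure = RegistrationResult(
        transform=SimilarityTransform.identity(),
        inlier_rmse=0.0,
        inlier_count=0,
        total_source_points=len(source),
        correspondence_threshold=params.distance_threshold_mm,
        converged=False,
    )
    corr_src, corr_tgt, mutual = feature_correspondences(source_fpfh, target_fpfh)
    if len(corr_src) < params.n_sample:
        return failure
    # sample from the high-precision mutual subset when it is large enough
    if mutual.sum() >= 4 * params.n_sample:
        pool_src, pool_tgt = corr_src[mutual], corr_tgt[mutual]
    else:
        pool_src, pool_tgt = corr_src, corr_tgt

    n_eval = min(params.eval_subsample, len(source))
    eval_idx = rng.choice(len(source), size=n_eval, replace=False)
    eval_pts = source.points[eval_idx]
    target_tree = cKDTree(target.points)

    best_transform = None
    best_count, best_rmse = -1, np.inf
    thr = params.distance_threshold_mm
    iters_needed = params.max_iters

    it = 0
    while it < min(iters_needed, params.max_iters):
        it += 1
        pick = rng.choice(len(pool_src), size=params.n_sample, replace=False)
        si = pool_src[pick]
        ti = pool_tgt[pick]
        if len(np.unique(ti)) < params.n_sample:
            continue
        sp, tp = source.points[si], target.points[ti]
        ok = True
        for a in range(params.n_sample):
            for b in range(a + 1, params.n_sample):
                ls = np.linalg.norm(sp[a] - sp[b])
                lt = np.linalg.norm(tp[a] - tp[b])
                if ls < 1e-9 or lt < 1e-9 or min(ls, lt) / max(ls, lt) < params.edge_length_ratio:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        try:
            cand = umeyama_similarity(sp, tp, with_scale=False)
        except DegenerateInputError:
            continue
        if np.any(np.linalg.norm(cand.apply(sp) - tp, axis=1) > thr):
            continue
        dist, _ = target_tree.query(cand.apply(eval_pts))
        inl = dist <= thr
        count = int(inl.sum())
        rmse = float(np.sqrt(np.mean(dist[inl] ** 2))) if count else np.inf
        if count > best_count or (count == best_count and rmse < best_rmse):
            best_transform, best_count, best_rmse = cand, count, rmse
            # termination from the correspondence-level inlier ratio: the
            # probability a sampled correspondence is consistent with the
            # best model, which is what drives all-inlier sample draws
            resid = np.linalg.norm(
                cand.apply(source.points[pool_src]) - target.points[pool_tgt], axis=1
            )
            w = float(np.mean(resid <= thr))
            if w >= 1.0:
                break
            if w > 0:
                denom = np.log(1.0 - w**params.n_sample)
                if denom < 0:
                    iters_needed = min(
                        params.max_iters,
                        int(np.ceil(np.log(1.0 - params.confidence) / denom)),
                    )

    if best_transform is None:
        return failure
    result = registration_metrics(source, target, best_transform, thr)
    result.n_iterations = it
    return result


# ---------------------------------------------------------------------------
# ICP refinement
# ---------------------------------------------------------------------------


def icp_refine(
    source: PointCloud,
    target: PointCloud,
    init: SimilarityTransform,
    max_corr_mm: float,
    max_iters: int = 50,
    rel_tol: float = 1e-6,
) -> RegistrationResult:
    """Point-to-point ICP with the scale frozen at ``init.scale``.

    Alternates nearest-neighbour correspondence (capped at ``max_corr_mm``)
    with a closed-form rigid update on the scaled source. The tracked
    objective is the distance-clamped RMSE sqrt(mean(min(d, max_corr)^2)),
    which both ICP half-steps can only decrease; its per-iteration values
    are exposed as ``result.objective_history``.
    """
    scale = init.scale
    rot, trans = init.rotation.copy(), init.translation.copy()
    tree = cKDTree(target.points)
    scaled = scale * source.points

    history: List[float] = []
    prev_obj = None
    n_done = 0
    converged = False
    for it in range(max_iters):
        moved = scaled @ rot.T + trans
        dist, idx = tree.query(moved)
        inlier = dist <= max_corr_mm
        if not inlier.any():
            if it == 0:
                raise DegenerateInputError(
                    "no correspondences within max_corr_mm at the initial "
                    "transform; provide a better initialization (scale/global "
                    "alignment)"
                )
            break
        pairs_src = scaled[inlier]
        pairs_tgt = target.points[idx[inlier]]
        try:
            update = umeyama_similarity(pairs_src, pairs_tgt, with_scale=False)
        except DegenerateInputError:
            break
        rot, trans = update.rotation, update.translation
        n_done = it + 1

        moved = scaled @ rot.T + trans
        dist, idx = tree.query(moved)
        obj = float(np.sqrt(np.mean(np.minimum(dist, max_corr_mm) ** 2)))
        history.append(obj)
        if prev_obj is not None and abs(prev_obj - obj) <= rel_tol * max(prev_obj, 1e-12):
            converged = True
            break
        prev_obj = obj

    final = SimilarityTransform(scale, rot, trans)
    result = registration_metrics(source, target, final, max_corr_mm)
    result.n_iterations = n_done
    result.converged = converged or n_done == max_iters
    result.objective_history = history
    return result


def symmetric_similarity_icp(
    source: PointCloud,
    target: PointCloud,
    init: SimilarityTransform,
    max_corr_mm: float,
    max_iters: int = 30,
    rel_tol: float = 1e-6,
    trim_factor: float = 3.0,
) -> SimilarityTransform:
    """Similarity ICP with symmetric correspondences, for scale refinement.

    Each iteration pairs every transformed source point with its nearest
    target point AND every target point with its nearest transformed source
    point, trims both sets at ``min(max_corr_mm, trim_factor * median)``,
    and solves the full Umeyama similarity on the union. The forward
    direction alone attenuates the scale when the source is noisy (the
    errors-in-variables effect against curved surfaces); the backward
    direction biases the opposite way, and the union cancels the bias to
    first order. Intended to run on voxel-downsampled clouds, whose
    centroids already average down the point noise.
    """
    tree_t = cKDTree(target.points)
    transform = init
    prev_scale = init.scale
    for _ in range(max_iters):
        moved = transform.apply(source.points)
        d_f, i_f = tree_t.query(moved)
        cut_f = min(max_corr_mm, trim_factor * float(np.median(d_f)))
        inl_f = d_f <= cut_f
        tree_s = cKDTree(moved)
        d_b, i_b = tree_s.query(target.points)
        within = d_b[d_b <= max_corr_mm]
        cut_b = (
            min(max_corr_mm, trim_factor * float(np.median(within)))
            if len(within)
            else max_corr_mm
        )
        inl_b = d_b <= cut_b
        if inl_f.sum() + inl_b.sum() < 3:
            break
        x = np.vstack([source.points[inl_f], source.points[i_b[inl_b]]])
        y = np.vstack([target.points[i_f[inl_f]], target.points[inl_b]])
        try:
            transform = umeyama_similarity(x, y, with_scale=True)
        except DegenerateInputError:
            break
        if abs(transform.scale - prev_scale) <= rel_tol * prev_scale:
            break
        prev_scale = transform.scale
    return transform


def piecewise_register(
    source_pieces: Sequence[PointCloud],
    target: PointCloud,
    init: SimilarityTransform,
    max_corr_mm: float = 1.5,
    max_iters: int = 50,
    rel_tol: float = 1e-6,
    per_piece_init: Optional[Sequence[SimilarityTransform]] = None,
) -> Tuple[List[RegistrationResult], PointCloud]:
    """Independently ICP-refine each reconstruction piece from a shared (or
    per-piece) initialization; local deformation such as a contracted
    branch is then absorbed piece by piece while landmark continuity comes
    from the shared global init.

    Returns the per-piece results and the composite coverage cloud (union
    of the transformed pieces; failed pieces are flagged with
    ``converged=False`` and excluded from the union)."""
    if len(source_pieces) == 0:
        raise ValueError("source_pieces must be nonempty")
    inits = per_piece_init or [init] * len(source_pieces)
    if len(inits) != len(source_pieces):
        raise ValueError("per_piece_init length must match source_pieces")

    results: List[RegistrationResult] = []
    moved_pieces = []
    for piece, piece_init in zip(source_pieces, inits):
        try:
            res = icp_refine(piece, target, piece_init, max_corr_mm, max_iters, rel_tol)
        except DegenerateInputError:
            res = RegistrationResult(
                transform=piece_init,
                inlier_rmse=0.0,
                inlier_count=0,
                total_source_points=len(piece),
                correspondence_threshold=max_corr_mm,
                converged=False,
            )
        results.append(res)
        if not res.zero_inliers:
            moved_pieces.append(res.transform.apply(piece.points))
    composite = PointCloud(
        np.vstack(moved_pieces) if moved_pieces else np.empty((0, 3))
    )
    return results, composite


def split_by_labels(cloud: PointCloud) -> List[PointCloud]:
    """Split a labelled cloud into per-label pieces (outlier label included
    as its own piece only if present), ordered by label value."""
    if cloud.labels is None:
        raise ValueError("cloud has no labels to split on")
    pieces = []
    for lab in np.unique(cloud.labels):
        pieces.append(cloud.select(cloud.labels == lab))
    return pieces
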