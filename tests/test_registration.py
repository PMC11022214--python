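"""Registration operators against brute-force oracles and known transforms."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import renalnav as rn
from renalnav.registration import FPFH_BINS, feature_correspondences
from renalnav.types import DegenerateInputError, PointCloud, SimilarityTransform


def rotation_angle_deg(r1, r2):
    return np.rad2deg(np.linalg.norm(Rotation.from_matrix(r1 @ r2.T).as_rotvec()))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


class TestVoxelDownsample:
    def test_two_points_one_voxel_gives_midpoint(self):
        cloud = PointCloud([[0.2, 0.2, 0.2], [0.6, 0.6, 0.6]])
        out = rn.voxel_downsample(cloud, 1.0)
        np.testing.assert_allclose(out.points, [[0.4, 0.4, 0.4]])

    def test_tiny_voxel_is_identity_up_to_order(self):
        rng = np.random.default_rng(0)
        pts = rng.random((50, 3)) * 10
        out = rn.voxel_downsample(PointCloud(pts), 1e-6)
        assert len(out) == 50
        assert {tuple(np.round(p, 9)) for p in out.points} == {
            tuple(np.round(p, 9)) for p in pts
        }

    @pytest.mark.parametrize("seed", range(5))
    def test_occupied_voxel_count_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((300, 3)) * 20 - 5
        voxel = 2.0
        out = rn.voxel_downsample(PointCloud(pts), voxel)
        occupied = {tuple(np.floor(p / voxel).astype(int)) for p in pts}
        assert len(out) == len(occupied)

    def test_centroids_match_dict_binning_oracle(self):
        rng = np.random.default_rng(9)
        pts = rng.random((200, 3)) * 8
        out = rn.voxel_downsample(PointCloud(pts), 1.5)
        bins = {}
        for p in pts:
            bins.setdefault(tuple(np.floor(p / 1.5).astype(int)), []).append(p)
        oracle = np.array([np.mean(v, axis=0) for k, v in sorted(bins.items())])
        np.testing.assert_allclose(out.points, oracle, atol=1e-12)

    def test_labels_survive(self):
        cloud = PointCloud([[0.1, 0, 0], [0.2, 0, 0], [5, 5, 5]], labels=[3, 3, -1])
        out = rn.voxel_downsample(cloud, 1.0)
        assert set(out.labels) == {3, -1}


class TestRadialNeighborFilter:
    def test_isolated_point_removed(self):
        rng = np.random.default_rng(1)
        cluster = rng.normal(0, 0.5, (40, 3))
        pts = np.vstack([cluster, [[50, 50, 50]]])
        out = rn.radial_neighbor_filter(PointCloud(pts), 2.0)
        assert len(out) == 40

    def test_radius_beyond_diameter_is_identity(self):
        rng = np.random.default_rng(2)
        pts = rng.random((30, 3)) * 5
        out = rn.radial_neighbor_filter(PointCloud(pts), 100.0)
        np.testing.assert_array_equal(out.points, pts)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_distance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((150, 3)) * 10
        radius = 1.2
        out = rn.radial_neighbor_filter(PointCloud(pts), radius)
        dists = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        np.fill_diagonal(dists, np.inf)
        keep = dists.min(axis=1) <= radius
        np.testing.assert_array_equal(out.points, pts[keep])


class TestEstimateNormals:
    def test_planar_cloud_gives_z_normals(self):
        g = np.linspace(0, 10, 12)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        out = rn.estimate_normals(PointCloud(pts), radius_mm=3.0)
        assert out.valid_normal_mask.all()
        assert np.allclose(np.abs(out.normals[:, 2]), 1.0, atol=1e-6)

    def test_sphere_normals_near_radial(self):
        rng = np.random.default_rng(3)
        dirs = rng.normal(size=(3000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = 10.0 * dirs
        out = rn.estimate_normals(PointCloud(pts), radius_mm=1.5)
        valid = out.valid_normal_mask
        dots = np.abs(np.einsum("ij,ij->i", out.normals[valid], dirs[valid]))
        angles = np.degrees(np.arccos(np.clip(dots, -1, 1)))
        assert np.percentile(angles, 99) < 5.0

    def test_orientation_locally_consistent(self):
        rng = np.random.default_rng(4)
        dirs = rng.normal(size=(2000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        out = rn.estimate_normals(PointCloud(10.0 * dirs), radius_mm=2.0)
        valid = out.valid_normal_mask
        # outward-consistent: signed radial component has a single sign
        signed = np.einsum("ij,ij->i", out.normals[valid], dirs[valid])
        assert (signed > 0).all() or (signed < 0).all()

    def test_two_point_cloud_all_invalid(self):
        out = rn.estimate_normals(PointCloud([[0, 0, 0], [1, 0, 0]]), radius_mm=5.0)
        assert not out.valid_normal_mask.any()


# ---------------------------------------------------------------------------
# FPFH
# ---------------------------------------------------------------------------


def naive_fpfh(points, normals, radius):
    """Loop-based FPFH from the published definition (independent oracle)."""
    n = len(points)
    spfh = np.zeros((n, 33))
    neighbors = [[] for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.linalg.norm(points[j] - points[i]) <= radius:
                neighbors[i].append(j)

    def pair_hist(i, j):
        p1, n1, p2, n2 = points[i], normals[i], points[j], normals[j]
        d = p2 - p1
        dist = np.linalg.norm(d)
        dhat = d / dist
        if abs(np.dot(n1, dhat)) < abs(np.dot(n2, dhat)):
            p1, n1, p2, n2 = p2, n2, p1, n1
            dhat = -dhat
        u = n1
        v = np.cross(dhat, u)
        v = v / np.linalg.norm(v)
        w = np.cross(u, v)
        alpha = np.dot(v, n2)
        phi = np.dot(u, dhat)
        theta = np.arctan2(np.dot(w, n2), np.dot(u, n2))
        h = np.zeros(33)
        h[min(int((alpha + 1) / 2 * 11), 10)] += 1
        h[11 + min(int((phi + 1) / 2 * 11), 10)] += 1
        h[22 + min(int((theta + np.pi) / (2 * np.pi) * 11), 10)] += 1
        return h

    for i in range(n):
        for j in neighbors[i]:
            spfh[i] += pair_hist(i, j)

    fpfh = spfh.copy()
    for i in range(n):
        if neighbors[i]:
            acc = np.zeros(33)
            for j in neighbors[i]:
                acc += spfh[j] / np.linalg.norm(points[j] - points[i])
            fpfh[i] += acc / len(neighbors[i])
    for b in range(3):
        block = fpfh[:, b * 11 : (b + 1) * 11]
        s = block.sum(axis=1, keepdims=True)
        nz = s[:, 0] > 0
        block[nz] = block[nz] / s[nz] * 100
    return fpfh


class TestFPFH:
    def test_planar_constant_geometry_concentrates_histograms(self):
        g = np.linspace(0, 6, 7)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
        cloud = PointCloud(pts, normals)
        feats = rn.compute_fpfh(cloud, radius_mm=2.5)
        for row in feats:
            for b in range(3):
                block = row[b * FPFH_BINS : (b + 1) * FPFH_BINS]
                assert block.max() == pytest.approx(100.0)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(5)
        dirs = rng.normal(size=(400, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = 8.0 * dirs
        cloud = PointCloud(pts, dirs)
        feats = rn.compute_fpfh(cloud, radius_mm=3.0)
        rot = Rotation.random(rng=np.random.default_rng(6)).as_matrix()
        moved = PointCloud(pts @ rot.T + [5.0, -3.0, 2.0], dirs @ rot.T)
        feats_moved = rn.compute_fpfh(moved, radius_mm=3.0)
        assert np.abs(feats - feats_moved).sum(axis=1).max() < 1e-6

    @pytest.mark.parametrize("seed", range(3))
    def test_small_cloud_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((5, 3)) * 3
        normals = rng.normal(size=(5, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        cloud = PointCloud(pts, normals)
        ours = rn.compute_fpfh(cloud, radius_mm=10.0)
        oracle = naive_fpfh(pts, normals, 10.0)
        np.testing.assert_allclose(ours, oracle, atol=1e-9)

    def test_isolated_point_gets_zero_row(self):
        pts = np.array([[0, 0, 0], [0.5, 0, 0], [0, 0.5, 0], [100, 100, 100.0]])
        normals = np.tile([0.0, 0.0, 1.0], (4, 1))
        feats = rn.compute_fpfh(PointCloud(pts, normals), radius_mm=2.0)
        assert feats[3].sum() == 0
        assert feats[0].sum() > 0

    def test_requires_normals(self):
        with pytest.raises(ValueError):
            rn.compute_fpfh(PointCloud(np.random.default_rng(0).random((10, 3))), 2.0)


# ---------------------------------------------------------------------------
# Scale and Umeyama
# ---------------------------------------------------------------------------


class TestScaleFromExtents:
    def test_doubled_cloud(self):
        rng = np.random.default_rng(7)
        pts = rng.random((500, 3)) * 10
        s = rn.estimate_scale_from_extents(PointCloud(pts), PointCloud(2 * pts))
        assert s == pytest.approx(2.0, abs=1e-6)

    def test_identity(self):
        rng = np.random.default_rng(8)
        pts = rng.random((200, 3))
        assert rn.estimate_scale_from_extents(
            PointCloud(pts), PointCloud(pts)
        ) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_robust_to_bounding_box_outliers(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.normal(0, 5, (1000, 3))
        rot = Rotation.random(rng=rng).as_matrix()
        tgt = 1.5 * src @ rot.T
        n_out = 50
        lo, hi = src.min(0), src.max(0)
        src_noisy = np.vstack([src, rng.uniform(1.2 * lo, 1.2 * hi, (n_out, 3))])
        s = rn.estimate_scale_from_extents(PointCloud(src_noisy), PointCloud(tgt))
        assert abs(s - 1.5) / 1.5 < 0.10

    def test_degenerate_cloud_rejected(self):
        with pytest.raises(DegenerateInputError):
            rn.estimate_scale_from_extents(
                PointCloud(np.zeros((10, 3))), PointCloud(np.random.rand(10, 3))
            )


class TestUmeyama:
    def test_identity_pairs(self):
        rng = np.random.default_rng(10)
        pts = rng.random((20, 3)) * 5
        t = rn.umeyama_similarity(pts, pts)
        assert t.scale == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_recovery_noise_free(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.random((15, 3)) * 10
        rot = Rotation.random(rng=rng).as_matrix()
        s, trans = rng.uniform(0.5, 2.0), rng.uniform(-20, 20, 3)
        dst = s * src @ rot.T + trans
        t = rn.umeyama_similarity(src, dst)
        assert abs(t.scale - s) < 1e-9
        assert rotation_angle_deg(t.rotation, rot) < 1e-7
        np.testing.assert_allclose(t.translation, trans, atol=1e-9)

    def test_noisy_triplet_matches_numeric_optimizer(self):
        rng = np.random.default_rng(11)
        src = rng.random((3, 3)) * 10
        dst = src @ Rotation.from_euler("z", 20, degrees=True).as_matrix().T
        dst = 1.2 * dst + [1, 2, 3] + rng.normal(0, 0.3, (3, 3))

        def objective(params):
            s = np.exp(params[0])
            rot = Rotation.from_rotvec(params[1:4]).as_matrix()
            return np.sum((s * src @ rot.T + params[4:7] - dst) ** 2)

        t = rn.umeyama_similarity(src, dst)
        x0 = np.concatenate(
            [[np.log(t.scale)], Rotation.from_matrix(t.rotation).as_rotvec(),
             t.translation]
        )
        # start the optimizer AWAY from our solution to keep it independent
        best = np.inf
        for trial in range(5):
            start = x0 * 0 + np.concatenate(
                [[0.1 * trial], rng.normal(0, 0.3, 3), rng.normal(0, 2, 3)]
            )
            res = minimize(objective, start, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
            best = min(best, res.fun)
        assert objective(x0) <= best + 1e-6

    def test_matches_skimage_estimator(self):
        from skimage.transform import SimilarityTransform as SkSim

        rng = np.random.default_rng(12)
        src = rng.random((30, 3)) * 10
        dst = 0.8 * src @ Rotation.random(rng=rng).as_matrix().T + [3, -1, 2]
        dst += rng.normal(0, 0.1, dst.shape)
        ours = rn.umeyama_similarity(src, dst)
        ref = SkSim.from_estimate(src, dst)
        np.testing.assert_allclose(ours.matrix, ref.params, atol=1e-9)

    def test_rigid_mode_keeps_unit_scale(self):
        rng = np.random.default_rng(13)
        src = rng.random((10, 3))
        dst = 2.0 * src
        t = rn.umeyama_similarity(src, dst, with_scale=False)
        assert t.scale == 1.0

    def test_collinear_points_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        with pytest.raises(DegenerateInputError):
            rn.umeyama_similarity(src, src + 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            rn.umeyama_similarity(np.zeros((2, 3)), np.ones((2, 3)))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


class TestRegistrationMetrics:
    def test_identity_on_same_cloud(self):
        rng = np.random.default_rng(14)
        pts = rng.random((100, 3)) * 10
        res = rn.registration_metrics(
            PointCloud(pts), PointCloud(pts), SimilarityTransform.identity(), 1.0
        )
        assert res.fitness == 1.0
        assert res.inlier_rmse == 0.0

    def test_all_points_beyond_threshold(self):
        src = PointCloud(np.zeros((5, 3)) + 100)
        tgt = PointCloud(np.zeros((5, 3)))
        res = rn.registration_metrics(src, tgt, SimilarityTransform.identity(), 1.0)
        assert res.inlier_count == 0
        assert res.inlier_rmse == 0.0
        assert res.zero_inliers

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_nearest_oracle(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.random((80, 3)) * 10
        tgt = rng.random((120, 3)) * 10
        thr = 1.0
        res = rn.registration_metrics(
            PointCloud(src), PointCloud(tgt), SimilarityTransform.identity(), thr
        )
        d = np.linalg.norm(src[:, None] - tgt[None], axis=2).min(axis=1)
        inl = d <= thr
        assert res.inlier_count == int(inl.sum())
        if inl.any():
            assert res.inlier_rmse == pytest.approx(np.sqrt(np.mean(d[inl] ** 2)))

    @pytest.mark.parametrize("seed", range(3))
    def test_invariants(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.random((60, 3)) * 4
        tgt = rng.random((60, 3)) * 4
        res = rn.registration_metrics(
            PointCloud(src), PointCloud(tgt), SimilarityTransform.identity(), 2.0
        )
        assert res.fitness * res.total_source_points == res.inlier_count
        assert res.inlier_rmse <= res.correspondence_threshold


# ---------------------------------------------------------------------------
# RANSAC and ICP (on phantom-derived surface clouds)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def surface_cloud(model_cloud):
    """Downsampled CT-model cloud with normals and features."""
    down = rn.voxel_downsample(model_cloud, 1.2)
    with_normals = rn.estimate_normals(down, 2.5, 30)
    feats = rn.compute_fpfh(with_normals, 5.0)
    return with_normals, feats


class TestRansac:
    def test_identity_clouds_recover_identity(self, surface_cloud):
        cloud, feats = surface_cloud
        res = rn.ransac_global_register(cloud, cloud, feats, feats, seed=0)
        assert res.fitness > 0.95
        assert rotation_angle_deg(res.transform.rotation, np.eye(3)) < 1.0
        assert np.linalg.norm(res.transform.translation) < 1.5

    def test_known_rigid_transform_recovered(self, surface_cloud):
        cloud, feats = surface_cloud
        rot = Rotation.from_euler("xyz", [30, -40, 70], degrees=True).as_matrix()
        t = SimilarityTransform(1.0, rot, [20.0, -15.0, 10.0])
        moved = cloud.transformed(t)
        moved_feats = rn.compute_fpfh(moved, 5.0)
        res = rn.ransac_global_register(moved, cloud, moved_feats, feats, seed=3)
        t_inv = t.inverse()
        assert rotation_angle_deg(res.transform.rotation, t_inv.rotation) < 1.0
        assert (
            np.linalg.norm(res.transform.translation - t_inv.translation)
            <= res.correspondence_threshold
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_pure_outlier_source_low_fitness(self, surface_cloud, seed):
        cloud, feats = surface_cloud
        rng = np.random.default_rng(seed)
        junk_pts = rng.uniform(-50, 50, (400, 3))
        junk = rn.estimate_normals(PointCloud(junk_pts), 8.0, 30)
        junk_feats = rn.compute_fpfh(junk, 12.0)
        res = rn.ransac_global_register(junk, cloud, junk_feats, feats, seed=seed)
        assert res.fitness < 0.2


class TestICP:
    def test_true_init_is_fixed_point(self, surface_cloud):
        cloud, _ = surface_cloud
        res = rn.icp_refine(cloud, cloud, SimilarityTransform.identity(), 1.5)
        assert res.inlier_rmse < 1e-9
        assert rotation_angle_deg(res.transform.rotation, np.eye(3)) < 1e-6

    def test_perturbed_init_recovers_truth(self, surface_cloud):
        cloud, _ = surface_cloud
        perturb = SimilarityTransform(
            1.0,
            Rotation.from_euler("y", 5, degrees=True).as_matrix(),
            [2.0, 0.0, -1.0],
        )
        res = rn.icp_refine(cloud, cloud, perturb, max_corr_mm=5.0)
        assert rotation_angle_deg(res.transform.rotation, np.eye(3)) < 0.1
        assert np.linalg.norm(res.transform.translation) < 0.05

    def test_objective_monotone_non_increasing(self, surface_cloud):
        cloud, _ = surface_cloud
        perturb = SimilarityTransform(
            1.0,
            Rotation.from_euler("x", 8, degrees=True).as_matrix(),
            [3.0, -2.0, 1.0],
        )
        res = rn.icp_refine(cloud, cloud, perturb, max_corr_mm=5.0)
        hist = np.asarray(res.objective_history)
        assert len(hist) >= 2
        assert np.all(np.diff(hist) <= 1e-12)

    def test_scale_frozen_at_init(self, surface_cloud):
        cloud, _ = surface_cloud
        init = SimilarityTransform(1.3, np.eye(3), np.zeros(3))
        target = PointCloud(1.3 * cloud.points)
        res = rn.icp_refine(cloud, target, init, max_corr_mm=3.0)
        assert res.transform.scale == 1.3

    def test_hopeless_init_raises_helpful_error(self, surface_cloud):
        cloud, _ = surface_cloud
        bad = SimilarityTransform(1.0, np.eye(3), [1e5, 0, 0])
        with pytest.raises(DegenerateInputError, match="initialization"):
            rn.icp_refine(cloud, cloud, bad, max_corr_mm=1.0)


class TestPiecewise:
    def test_single_piece_matches_plain_icp(self, surface_cloud):
        cloud, _ = surface_cloud
        init = SimilarityTransform(
            1.0, Rotation.from_euler("z", 3, degrees=True).as_matrix(), [1.0, 0, 0]
        )
        results, composite = rn.piecewise_register([cloud], cloud, init, 3.0)
        plain = rn.icp_refine(cloud, cloud, init, 3.0)
        assert results[0].inlier_rmse == pytest.approx(plain.inlier_rmse, abs=1e-9)
        assert len(composite) == len(cloud)

    def test_undeformed_pieces_agree_with_global(self, phantom_bundle):
        """Pieces = whole calyceal subtrees (each anchored at a junction
        landmark); on an undeformed cloud their refined transforms must all
        agree with the single global registration. The target is sampled
        from the same lumen surface so the check isolates the piecewise
        mechanics from CT rasterization error."""
        _ct, gt, cloud, _traj = phantom_bundle  # identity transform, no noise
        down = rn.voxel_downsample(cloud, 1.0)
        init = SimilarityTransform(
            1.0, Rotation.from_euler("x", 2, degrees=True).as_matrix(), [0.5, 0, 0]
        )
        global_res = rn.icp_refine(cloud, down, init, 3.0)
        n_minor = 2
        groups = [
            [0, 1] + [2 + k for k in range(n_minor)],
            [2 + n_minor + k for k in range(1 + n_minor)],
            [3 + 2 * n_minor + k for k in range(1 + n_minor)],
        ]
        pieces = [
            cloud.select(np.isin(cloud.labels, g)) for g in groups
        ]
        results, _ = rn.piecewise_register(pieces, down, init, 3.0)
        for res in results:
            assert rotation_angle_deg(
                res.transform.rotation, global_res.transform.rotation
            ) < 0.5
            assert np.linalg.norm(
                res.transform.translation - global_res.transform.translation
            ) < 0.5

    def test_contracted_branch_improves_with_pieces(self, phantom_bundle):
        """With one branch contracted, per-branch refinement must beat a
        single global registration on mean surface distance."""
        _ct, gt, _cloud, _traj = phantom_bundle
        traj = gt.true_trajectory_ct
        target_branch = int(gt.tree.branch_id_per_edge[1])
        cloud, _rt = rn.synthesize_reconstruction_cloud(
            gt, traj, contraction={target_branch: 0.85}, seed=2
        )
        model = rn.voxel_downsample(
            PointCloud(
                rn.surface_sample_points(
                    rn.extract_isosurface(gt.collecting_mask, smooth_sigma=0.5),
                    30000,
                    seed=0,
                ).points
            ),
            1.0,
        )
        init = SimilarityTransform.identity()
        global_res = rn.icp_refine(cloud, model, init, 2.0)
        moved_global = global_res.transform.apply(cloud.points)

        pieces = rn.split_by_labels(cloud)
        _results, composite = rn.piecewise_register(
            pieces, model, global_res.transform, 2.0
        )

        from scipy.spatial import cKDTree

        tree = cKDTree(model.points)
        d_global = tree.query(moved_global)[0].mean()
        d_pieces = tree.query(composite.points)[0].mean()
        assert d_pieces < d_global

    def test_empty_piece_list_rejected(self, surface_cloud):
        cloud, _ = surface_cloud
        with pytest.raises(ValueError):
            rn.piecewise_register([], cloud, SimilarityTransform.identity(), 1.0)


class TestFeatureCorrespondences:
    def test_self_match_is_mutual_identity(self, surface_cloud):
        _cloud, feats = surface_cloud
        si, ti, mutual = feature_correspondences(feats, feats)
        assert mutual.all()
        np.testing.assert_array_equal(si, ti)
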