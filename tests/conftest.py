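"""Shared fixtures: small phantoms reused across the suite."""

import numpy as np
import pytest

import renalnav as rn


@pytest.fixture(scope="session")
def default_spec():
    return rn.PhantomSpec(seed=0)


@pytest.fixture(scope="session")
def phantom_bundle(default_spec):
    """Clean phantom under the identity transform: (ct, gt, cloud, traj)."""
    return rn.make_phantom(default_spec)


@pytest.fixture(scope="session")
def phantom_tree(default_spec):
    return rn.build_tree_skeleton(default_spec)


@pytest.fixture(scope="session")
def model_cloud(phantom_bundle):
    """CT-side model point sample for the clean phantom."""
    ct, gt, _cloud, _traj = phantom_bundle
    mask = rn.extract_collecting_system(ct, gt.kidney_mask)
    mesh = rn.extract_isosurface(mask, smooth_sigma=0.5)
    return rn.surface_sample_points(mesh, 30000, seed=0)


def distance_to_lumen_surface(tree, pts):
    """Unsigned distance from points to the union-of-capsules surface
    (independent analytic oracle used by several tests)."""
    pts = np.asarray(pts, dtype=float)
    signed = np.full(len(pts), np.inf)
    for ei in range(tree.n_branches):
        a, b = tree.segment(ei)
        ab = b - a
        t = np.clip((pts - a) @ ab / (ab @ ab), 0.0, 1.0)
        d = np.linalg.norm(pts - (a + t[:, None] * ab), axis=1)
        signed = np.minimum(signed, d - tree.radius_per_edge[ei])
    return np.abs(signed)


@pytest.fixture(scope="session")
def lumen_surface_distance():
    return distance_to_lumen_surface
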