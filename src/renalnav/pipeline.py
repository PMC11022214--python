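"""End-to-end drivers: the full registration chain and the staged pipeline.

``register_clouds`` chains the individual registration operations the way
the method prescribes: radial outlier filter -> voxel downsample -> scale
initialization (robust extents, or manual correspondences when supplied)
-> FPFH + RANSAC global alignment -> ICP refinement -> similarity re-fit
on the converged correspondences -> final ICP. ``run_pipeline`` executes
simulate/extract/mesh/register/localize/evaluate end to end from a single
config and records a reproducible manifest.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import io as rio
from .collecting_system import (
    dice_coefficient,
    extract_collecting_system,
    threshold_kidney_standin,
)
from .localization import (
    DEFAULT_TAU_MM,
    coverage_fraction,
    trajectory_error,
    transform_trajectory,
)
from .meshing import dilate_mesh_along_normals, extract_isosurface, surface_sample_points
from .phantom import OUTLIER_LABEL, PhantomSpec, make_phantom, random_similarity_transform
from .registration import (
    RansacParams,
    compute_fpfh,
    estimate_normals,
    estimate_scale_from_extents,
    icp_refine,
    piecewise_register,
    radial_neighbor_filter,
    registration_metrics,
    split_by_labels,
    symmetric_similarity_icp,
    umeyama_similarity,
    voxel_downsample,
)
from .types import (
    PointCloud,
    RegistrationResult,
    SimilarityTransform,
)

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# Full registration chain
# ---------------------------------------------------------------------------


@dataclass
class RegistrationParams:
    """Tunables of the registration chain, in mm where dimensional.

    Defaults are scaled to the 1 mm phantom sampling pitch; every value is
    configurable for other resolutions.
    """

    filter_radius_mm: float = 1.5
    downsample_voxel_mm: float = 1.0
    normal_radius_mm: float = 2.5
    normal_k_max: int = 30
    fpfh_radius_mm: float = 5.0
    ransac_distance_mm: float = 1.5
    ransac_edge_ratio: float = 0.9
    ransac_max_iters: int = 100_000
    icp_max_corr_mm: float = 1.5
    icp_max_iters: int = 50
    icp_rel_tol: float = 1e-6
    refit_scale: bool = True
    # extent-based scale is biased when the reconstruction only covers part
    # of the model (the endoscope never sees the entry region), so the
    # global stage tries a small grid of scale hypotheses around it and
    # keeps the consensus winner — an automated version of tuning the
    # scales from the cloud dimensions
    scale_hypotheses: Tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 1.1, 1.2)


@dataclass
class ChainOutput:
    """Result of the full chain plus the intermediates tests care about."""

    result: RegistrationResult
    transform: SimilarityTransform
    filtered_source: PointCloud
    source_down: PointCloud
    target_down: PointCloud
    scale_init: float
    global_result: Optional[RegistrationResult] = None
    piece_results: Optional[List[RegistrationResult]] = None
    composite_result: Optional[RegistrationResult] = None
    composite_cloud: Optional[PointCloud] = None


def register_clouds(
    source: PointCloud,
    target: PointCloud,
    params: Optional[RegistrationParams] = None,
    seed: int = 0,
    correspondences: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    piecewise: bool = False,
) -> ChainOutput:
    """Align a reconstruction cloud to the CT model cloud.

    With ``correspondences`` (manually picked source/target point pairs)
    the global stage is a correspondence-seeded similarity fit, replacing
    RANSAC — the route used when feature-based alignment is unstable on
    deformed clouds. Otherwise the scale comes from robust principal-axis
    extents and the global pose from FPFH-matched RANSAC.

    ``piecewise=True`` additionally refines each labelled branch of the
    (filtered) source independently from the global alignment and reports
    composite metrics over the union of pieces; synthetic outlier labels
    are excluded from the pieces.
    """
    params = params or RegistrationParams()

    filtered = radial_neighbor_filter(source, params.filter_radius_mm)
    if len(filtered) < 3:
        raise ValueError("too few points survive the radial neighbour filter")
    src_down = voxel_downsample(filtered, params.downsample_voxel_mm)
    tgt_down = voxel_downsample(target, params.downsample_voxel_mm)

    if correspondences is not None:
        src_pts, tgt_pts = correspondences
        init = umeyama_similarity(src_pts, tgt_pts, with_scale=True)
        scale_init = init.scale
        global_result = None
    else:
        scale_ext = estimate_scale_from_extents(src_down, tgt_down)
        tgt_n = estimate_normals(tgt_down, params.normal_radius_mm, params.normal_k_max)
        tgt_f = compute_fpfh(tgt_n, params.fpfh_radius_mm)

        best = None
        for mult in params.scale_hypotheses:
            s_hyp = mult * scale_ext
            prescale = SimilarityTransform(s_hyp, np.eye(3), np.zeros(3))
            src_scaled = PointCloud(prescale.apply(src_down.points))
            src_n = estimate_normals(
                src_scaled, params.normal_radius_mm, params.normal_k_max
            )
            src_f = compute_fpfh(src_n, params.fpfh_radius_mm)
            res = ransac_global(
                src_scaled, tgt_down, src_f, tgt_f, params, seed=seed
            )
            if best is None or (res.inlier_count, -res.inlier_rmse) > (
                best[0].inlier_count, -best[0].inlier_rmse
            ):
                best = (res, s_hyp, prescale)
                if res.fitness >= 0.8:  # decisive consensus; later
                    break               # hypotheses cannot do better
        global_result, scale_init, prescale = best
        init = global_result.transform.compose(prescale)

    refined = icp_refine(
        src_down, tgt_down, init,
        params.icp_max_corr_mm, params.icp_max_iters, params.icp_rel_tol,
    )
    transform = refined.transform

    if params.refit_scale:
        transform = symmetric_similarity_icp(
            src_down, tgt_down, transform,
            params.icp_max_corr_mm, params.icp_max_iters, params.icp_rel_tol,
        )

    result = registration_metrics(filtered, target, transform, params.icp_max_corr_mm)
    out = ChainOutput(
        result=result,
        transform=transform,
        filtered_source=filtered,
        source_down=src_down,
        target_down=tgt_down,
        scale_init=scale_init,
        global_result=global_result,
    )

    if piecewise:
        if filtered.labels is None:
            raise ValueError("piecewise registration needs a labelled source cloud")
        branch_cloud = filtered.select(filtered.labels != OUTLIER_LABEL)
        pieces = split_by_labels(branch_cloud)
        piece_results, composite = piecewise_register(
            pieces, target, transform,
            params.icp_max_corr_mm, params.icp_max_iters, params.icp_rel_tol,
        )
        out.piece_results = piece_results
        out.composite_cloud = composite
        out.composite_result = registration_metrics(
            composite, target, SimilarityTransform.identity(), params.icp_max_corr_mm
        )
    return out


def ransac_global(source, target, source_fpfh, target_fpfh, params, seed=0):
    """RANSAC global registration with parameters lifted from
    :class:`RegistrationParams`."""
    from .registration import ransac_global_register

    rp = RansacParams(
        distance_threshold_mm=params.ransac_distance_mm,
        edge_length_ratio=params.ransac_edge_ratio,
        max_iters=params.ransac_max_iters,
    )
    return ransac_global_register(source, target, source_fpfh, target_fpfh, rp, seed=seed)


# ---------------------------------------------------------------------------
# Staged pipeline
# ---------------------------------------------------------------------------


@dataclass
class MeshParams:
    #: "ct" contours the CT intensities at the lumen class boundary
    #: (sub-voxel accurate); "mask" contours the binary mask (the only
    #: option when no intensity volume is available)
    surface_from: str = "ct"
    smooth_sigma_voxels: float = 0.0
    dilate_mm: float = 0.0
    n_sample_points: int = 50_000


def build_ct_model(
    ct,
    kidney_mask,
    kernel: Tuple[int, int, int] = (9, 9, 5),
    n_bins: int = 256,
    mesh_params: Optional[MeshParams] = None,
    seed: int = 0,
):
    """CT side of the pipeline: extract the collecting system, mesh its
    surface, and sample the mesh into the registration target cloud.

    Returns ``(collecting_mask, mesh, model_cloud)``. With
    ``surface_from="ct"`` the mesh is a grayscale isosurface at the
    three-class Otsu parenchyma/lumen boundary, which localizes the wall
    with sub-voxel accuracy; ``"mask"`` falls back to the binary-mask
    isosurface (optionally smoothed).
    """
    from .collecting_system import binary_dilate, multiclass_otsu
    from .meshing import lumen_isosurface

    mesh_params = mesh_params or MeshParams()
    cs_mask = extract_collecting_system(ct, kidney_mask, kernel, n_bins)
    if mesh_params.surface_from == "ct":
        dilated = binary_dilate(kidney_mask, kernel)
        thresholds = multiclass_otsu(ct.data[dilated.data], k=3, n_bins=n_bins)
        mesh = lumen_isosurface(ct, cs_mask, level=float(thresholds[-1]))
    elif mesh_params.surface_from == "mask":
        mesh = extract_isosurface(
            cs_mask, smooth_sigma=mesh_params.smooth_sigma_voxels
        )
    else:
        raise ValueError(f"unknown surface_from {mesh_params.surface_from!r}")
    if mesh_params.dilate_mm > 0:
        mesh = dilate_mesh_along_normals(mesh, mesh_params.dilate_mm)
    model_cloud = surface_sample_points(mesh, mesh_params.n_sample_points, seed=seed)
    return cs_mask, mesh, model_cloud


@dataclass
class PipelineConfig:
    """One declarative description of a full run.

    Exactly one of ``phantom`` (a :class:`PhantomSpec` plus simulation
    settings) or ``inputs`` (paths to real CT / mask / reconstruction /
    trajectory files) must be given.
    """

    phantom: Optional[dict] = None
    inputs: Optional[dict] = None
    seed: int = 0
    extract_kernel: Tuple[int, int, int] = (9, 9, 5)
    otsu_bins: int = 256
    mesh: MeshParams = field(default_factory=MeshParams)
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    tau_mm: float = DEFAULT_TAU_MM
    piecewise: bool = False

    def validate(self) -> None:
        if (self.phantom is None) == (self.inputs is None):
            raise ValueError(
                "config must specify exactly one of 'phantom' or 'inputs'"
            )


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stage_seconds: Dict[str, float] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)  # filename -> sha256
    summary: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute simulate -> extract -> mesh -> register -> localize
    (-> evaluate, when ground truth exists) and write all artifacts plus a
    manifest into ``out_dir``. Reproducible: same config + seed gives the
    same outputs and digests."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=_config_snapshot(config), version=__version__, seed=config.seed
    )

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                manifest.stage_seconds[name] = round(
                    time.perf_counter() - self_inner.t0, 3
                )
                if exc is not None:
                    raise RuntimeError(
                        f"pipeline stage '{name}' failed: {exc}"
                    ) from exc

        return _Timer()

    gt = None
    recon_traj = None
    # -- simulate or load ---------------------------------------------------
    with stage("simulate" if config.phantom else "load"):
        if config.phantom is not None:
            ph = dict(config.phantom)
            spec_fields = {
                k: v for k, v in ph.items() if k in PhantomSpec.__dataclass_fields__
            }
            spec = PhantomSpec(**spec_fields)
            spec.seed = config.seed
            transform = random_similarity_transform(
                config.seed, scale=ph.get("transform_scale", 1.0)
            )
            contraction = ph.get("contraction") or None
            if contraction:
                contraction = {int(k): float(v) for k, v in contraction.items()}
            ct, gt, recon_cloud, recon_traj = make_phantom(
                spec,
                frames_per_branch=ph.get("frames_per_branch", 6),
                transform=transform,
                noise_sigma_mm=ph.get("recon_noise_mm", 0.0),
                outlier_fraction=ph.get("outlier_fraction", 0.0),
                contraction=contraction,
                n_surface_points=ph.get("n_surface_points", 20000),
            )
            kidney_mask = gt.kidney_mask
            rio.save_volume(ct, out / "ct.nii")
            rio.save_volume(gt.collecting_mask, out / "collecting_mask_gt.nii", as_mask=True)
            rio.save_volume(kidney_mask, out / "kidney_mask.nii", as_mask=True)
            rio.save_point_cloud(recon_cloud, out / "reconstruction.ply")
            rio.save_trajectory(recon_traj, out / "trajectory_recon.csv")
            rio.save_trajectory(gt.true_trajectory_ct, out / "trajectory_ct_true.csv")
            rio.save_transform(gt.true_transform, out / "true_transform.json")
        else:
            paths = config.inputs
            ct = rio.load_volume(paths["ct"])
            if "kidney_mask" in paths:
                kidney_mask = rio.load_volume(paths["kidney_mask"], as_mask=True)
            else:
                kidney_mask = threshold_kidney_standin(
                    ct, float(paths.get("kidney_level", 50.0))
                )
            recon_cloud = rio.load_point_cloud(paths["reconstruction"])
            if "trajectory" in paths:
                p = str(paths["trajectory"])
                recon_traj = (
                    rio.load_colmap_images(p)
                    if p.endswith(".txt")
                    else rio.load_trajectory(p)
                )

    # -- extract + mesh -----------------------------------------------------
    with stage("extract"):
        cs_mask, mesh, model_cloud = build_ct_model(
            ct,
            kidney_mask,
            kernel=config.extract_kernel,
            n_bins=config.otsu_bins,
            mesh_params=config.mesh,
            seed=config.seed,
        )
        rio.save_volume(cs_mask, out / "collecting_mask.nii", as_mask=True)
        if gt is not None:
            manifest.summary["extraction_dice"] = dice_coefficient(
                cs_mask, gt.collecting_mask
            )

    with stage("mesh"):
        rio.save_mesh(mesh, out / "model.ply")
        rio.save_point_cloud(model_cloud, out / "model_points.ply")

    # -- register -----------------------------------------------------------
    with stage("register"):
        correspondences = None
        if config.inputs and "correspondences" in config.inputs:
            correspondences = rio.load_correspondences(
                config.inputs["correspondences"]
            )
        chain = register_clouds(
            recon_cloud,
            model_cloud,
            config.registration,
            seed=config.seed,
            correspondences=correspondences,
            piecewise=config.piecewise and recon_cloud.labels is not None,
        )
        rio.save_transform(chain.transform, out / "transform.json")
        reg_report = chain.result.to_dict()
        if chain.composite_result is not None:
            reg_report["piecewise"] = chain.composite_result.to_dict()
        rio.save_json(reg_report, out / "registration.json")
        manifest.summary["inlier_rmse_mm"] = chain.result.inlier_rmse
        manifest.summary["fitness"] = chain.result.fitness

    # -- localize -----------------------------------------------------------
    with stage("localize"):
        observed = (
            chain.composite_cloud
            if chain.composite_cloud is not None
            else chain.filtered_source.transformed(chain.transform)
        )
        coverage = coverage_fraction(model_cloud, observed, config.tau_mm)
        rio.save_json(coverage.to_dict(), out / "coverage.json")
        manifest.summary["covered_fraction"] = coverage.covered_fraction
        if recon_traj is not None:
            est_traj = transform_trajectory(recon_traj, chain.transform)
            rio.save_trajectory(est_traj, out / "trajectory_estimated.csv")

    # -- evaluate (ground truth only) ---------------------------------------
    if gt is not None and recon_traj is not None:
        with stage("evaluate"):
            err = trajectory_error(est_traj, gt.true_trajectory_ct)
            rio.save_json(
                {
                    "position": err["position"],
                    "orientation": err["orientation"],
                    "n_frames": err["n_frames"],
                },
                out / "trajectory_error.json",
            )
            manifest.summary["median_position_error_mm"] = err["position"]["median"]

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.outputs[f.name] = _digest(f)
    rio.save_json(manifest.to_dict(), out / "manifest.json")
    return manifest


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = asdict(config)
    return snap
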