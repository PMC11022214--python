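# Methods

This note documents the models, parameter choices and numerical decisions
behind `renalnav`, and what the synthetic phantom does and does not
establish about real data.

## The phantom

The collecting system is modelled as a rooted tree of capsules: straight
centreline segments with constant radius, rasterized by distance to the
segment. One pelvis trunk (radius = upper end of `radius_range`,
default 5 mm) carries `n_major_branches` major calyces (default 3,
radius √(r_min·r_max) ≈ 3 mm) which each carry `n_minor_per_major` minor
calyces (default 2, radius 1.8 mm). Branch directions are drawn in cones
around the parent direction (majors 32–58° off the trunk, minors 20–45°
off the major) with the z-component compressed to fit thin axial fields
of view. Branch lengths are uniform in `branch_length_range`
(default 14–22 mm, minors at 60 %). All randomness flows from a single
spec seed through named substreams, so identical specs are bit-identical.

The CT is a three-level image — background 0, a parenchyma ellipsoid
hugging the tree at 100, lumen 300 — plus additive Gaussian noise
(default σ = 20). This emulates the *contrast structure* of delayed-phase
CT: the pooled contrast makes the lumen the brightest class by a wide
margin. The masks are noise-free. The default grid is 128×128×64 at
1 mm isotropic, chosen for desk-scale runtimes; `clinical_spec()` gives a
512×512×82 grid at 0.76×0.76×5 mm for resolution studies.

The endoscope trajectory walks the centrelines depth-first, emitting
`frames_per_branch` poses per branch segment on the forward pass, looking
along the tangent. With `include_return=True` it also emits withdrawal
poses looking back toward the root — the inspect-on-entry-and-withdrawal
pattern of a thorough endoscopy. The default is forward-only, which
leaves the region behind the first pose unseen; this is deliberate, as it
produces the partial-coverage reconstructions that make scale estimation
genuinely hard (see below).

The synthetic reconstruction samples the lumen surface (tube walls plus
hemispherical blind-end caps) area-uniformly, keeps points visible under
a distance-and-cone viewing model (15 mm range, 70° half-angle; no
occlusion), optionally contracts each branch's points radially toward its
axis (emulating contraction deformation from fast camera motion), maps
everything through the **inverse** of a hidden similarity transform, adds
isotropic Gaussian noise, and appends uniform outliers in a 20 %-inflated
bounding box (emulating false matches on floating debris). Registering
the cloud back to the CT must therefore recover the hidden transform.

**What the phantom does not model:** photometric effects (the SfM step is
bypassed entirely — the cloud is given), occlusion, fluid motion,
non-rigid deformation beyond per-branch radial contraction, anatomical
variation of real pelvicalyceal systems, and partial-volume effects of
thick-slice CT. Passing tests demonstrate the geometry pipeline is
correct and well-conditioned under these idealized degradations, not that
a particular clinical video will reconstruct.

## Extraction

Box dilation uses a separable max-filter; the 9×9×5 default puts the
small extent on the slice axis (clinical slices are ~5 mm against
~0.76 mm in-plane). Multi-level Otsu bins the intensities inside the
dilated kidney into 256 uniform bins and exhaustively maximizes
between-class variance (vectorized over all boundary pairs for three
classes); variance ties — which occur when a class boundary slides across
empty bins — are broken toward the lexicographically smallest boundary
pair. Thresholds are reported as bin centres (the scikit-image
convention, against which the implementation is cross-checked). A final
largest-26-connected-component step enforces a single structure; whether
the original post-processing used such a step is not documented, so it is
an explicit choice here. The whole-kidney mask is taken as given (from
the phantom, or any segmentation tool); `threshold_kidney_standin` is a
phantom-only surrogate and is labelled as such.

## Meshing

The registration target surface is contoured from the **CT intensities**
at the Otsu parenchyma/lumen boundary (restricted to a small dilation of
the extracted component), not from the binary mask. The reason is
quantitative: a binary mask quantizes the wall to the voxel grid
(~0.2–0.3 mm RMS, worst at the high-curvature calyceal tips), and
Gaussian pre-smoothing trades the staircase for a curvature-proportional
inward bias (~σ²κ ≈ 0.3 mm at 1.8 mm tips) — both of which propagate into
a 1–2 % scale error in registration through the extremity lever arm.
Grayscale marching cubes interpolates the class crossing inside each
voxel and recovers the wall at ~0.2 mm RMS with negligible bias (measured
against the analytic phantom surface). The mask route remains available
(`MeshParams(surface_from="mask")`, optional smoothing) for mask-only
inputs.

Mesh dilation moves each vertex by `step_mm` along its unit angle-
weighted vertex normal; "add the normals" is read as unit normals with a
configurable step so behaviour is independent of voxel spacing. Faces are
unchanged and self-intersections at concavities are tolerated because the
registration consumes point samples, not mesh topology. Surface sampling
is area-weighted with barycentric-interpolated normals, deterministic per
seed.

## Registration

Defaults (all configurable, scaled to the 1 mm phantom pitch): radial
filter radius 1.5 mm; downsample voxel 1.0 mm; normal radius 2.5 mm
(k ≤ 30); FPFH radius 5.0 mm; RANSAC distance threshold 1.5 mm,
edge-length ratio 0.9, up to 100 000 draws with confidence-based early
termination; ICP max correspondence 1.5 mm (1.0 mm in the clean
benchmark), 50 iterations, relative tolerance 1e-6.

Three decisions deserve explanation:

- **Scale hypotheses.** The extent-ratio scale guess assumes both clouds
  cover the same structure; a forward-looking endoscope never sees the
  entry region, so the reconstruction is systematically shorter and the
  ratio overestimates the scale (by up to ~30 % on forward-only
  phantoms). A single wrong prescale is fatal to RANSAC because correct
  correspondence triples then fail the edge-length-ratio check. The
  global stage therefore sweeps multipliers (1.0, 0.9, 0.8, 0.7, 1.1,
  1.2) of the extent estimate and keeps the consensus winner, stopping
  early on a decisive fit — an automated version of tuning the scales
  from the cloud dimensions.

- **Mutual-nearest correspondences.** Tube walls are self-similar, so
  one-way nearest-FPFH matches are only ~5 % correct; reciprocal matches
  concentrate on junctions and tips and are several times more precise.
  RANSAC samples its triples from the mutual subset (falling back to all
  matches when too few exist) and derives its termination bound from the
  correspondence-level inlier ratio of the current best model.

- **Symmetric similarity ICP.** Point-to-point ICP with a scale estimated
  from forward correspondences attenuates the scale under point noise
  (an errors-in-variables effect against curved surfaces, roughly
  σ²/r²-sized on thin tubes). Matching in both directions
  (source→target and target→source, trimmed at 3× the median residual)
  and fitting the Umeyama similarity on the union cancels the bias to
  first order. The refit runs on the voxel-downsampled clouds because
  centroid averaging also suppresses the point noise itself; on the
  dense clouds the backward selection bias dominates and inflates the
  scale instead.

Rigid ICP freezes the scale at its initialization and tracks the clamped
objective √mean(min(d, d_max)²), which both ICP half-steps can only
decrease; the per-iteration values are exposed for verification.
RANSAC, sampling and all KD-tree tie-breaks are deterministic per seed
(feature ties resolve to the smallest index). Zero-inlier metrics report
RMSE 0 with an explicit flag rather than NaN.

Piecewise registration refines each labelled branch independently from
the shared global alignment, absorbing per-branch contraction while the
global init preserves junction landmarks; failed pieces (no
correspondences) are flagged and excluded from the composite cloud.
Piece labels are taken as given (ground-truth branch labels on phantoms,
any spatial clustering on real data).

## Localization and coverage

Trajectories transform as p ↦ s·R·p + t with orientations rotated and
renormalized; positions are camera centres. Orientation error is the
geodesic angle with the quaternion sign ambiguity removed by the absolute
dot product. Coverage is defined over model *surface* points (fraction
within τ of the registered reconstruction, τ default 2 mm = twice the
sampling pitch), which matches how covered volume is visualized and stays
well-defined for partial reconstructions. The COLMAP `images.txt` reader
converts the stored world-to-camera pose (q, t) to camera centres −Rᵀt
and world-from-camera quaternions, unit-tested against a hand-built
two-image fixture.

## Pipeline and reproducibility

One declarative config drives simulate → extract → mesh → register →
localize → evaluate; exactly one of a phantom spec or real-input paths
must be present. All randomness derives from the single top-level seed.
The manifest records the config snapshot, per-stage wall times and
SHA-256 digests of every artifact; volumes are written as uncompressed
NIfTI so digests are bit-stable across reruns. Problem sizes in the
shipped study conditions — 128×128×64 phantoms, ~20 000 surface samples,
50 000-point model clouds, ~3 000-point downsampled registration clouds —
were chosen so the full suite and the acceptance script each run in a few
minutes on a single CPU.

## Known limitations

- The viewing model is distance + cone without occlusion; coverage of
  branches seen "across" a junction is counted as visualized.
- Scale recovery degrades when the reconstruction covers much less of the
  structure than the forward-pass phantoms emulate; the hypothesis sweep
  widens the basin but does not remove the limitation (manual
  correspondences are then the fallback, as in practice).
- Piecewise refinement corrects per-branch *radial* contraction; it does
  not model bending or longitudinal stretch.
- The kidney stand-in threshold segmentation is for phantoms only; real
  use requires an external whole-kidney segmentation.
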