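"""Generate a synthetic collecting-system phantom and inspect its parts.

Builds the branched lumen skeleton (pelvis trunk, major and minor
calyces), rasterizes it into a noisy delayed-phase-style CT with clean
ground-truth masks, threads an endoscope trajectory through the branches,
and synthesizes an SfM-style reconstruction cloud in a hidden similarity
frame.
"""

import numpy as np

import renalnav as rn

spec = rn.PhantomSpec(seed=0)  # 128x128x64 @ 1 mm, intensities 0/100/300
hidden = rn.random_similarity_transform(seed=0, scale=1.1)
ct, gt, recon_cloud, recon_traj = rn.make_phantom(
    spec, transform=hidden, noise_sigma_mm=0.3, outlier_fraction=0.05
)

tree = gt.tree
print(f"skeleton: {tree.n_branches} branches, radii "
      f"{tree.radius_per_edge.min():.1f}-{tree.radius_per_edge.max():.1f} mm")
print(f"CT: shape {ct.shape}, intensity range "
      f"[{ct.data.min():.0f}, {ct.data.max():.0f}]")
print(f"lumen voxels: {int(gt.collecting_mask.data.sum())}, "
      f"kidney voxels: {int(gt.kidney_mask.data.sum())}")
print(f"trajectory: {len(gt.true_trajectory_ct)} frames")
n_outliers = int((recon_cloud.labels == rn.OUTLIER_LABEL).sum())
print(f"reconstruction: {len(recon_cloud)} points "
      f"({n_outliers} synthetic outliers), hidden scale {hidden.scale}")

# the reconstruction lives in its own frame; mapping it back with the
# hidden transform must land on the lumen surface (up to the 0.3 mm noise)
back = hidden.apply(recon_cloud.points[recon_cloud.labels != rn.OUTLIER_LABEL])
span = back.max(axis=0) - back.min(axis=0)
print(f"reconstruction span in CT frame: {span.round(1)} mm")
print("-> every quantity above has ground truth attached, so each pipeline "
      "stage can be scored by parameter recovery.")
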