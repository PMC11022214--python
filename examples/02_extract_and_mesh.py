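"""Extract the collecting system from a noisy phantom CT and build the
3-D model used as the registration target.

The extraction follows the delayed-phase logic: dilate the kidney mask
(9x9x5 voxels), split the intensities inside it into three Otsu classes,
keep the brightest class (pooled contrast), keep the largest 26-connected
component. The model surface is then contoured from the CT intensities at
the parenchyma/lumen class boundary and sampled into a point cloud.
"""

import renalnav as rn

spec = rn.PhantomSpec(seed=3, noise_sigma=20.0)
tree = rn.build_tree_skeleton(spec)
ct, cs_truth, kidney = rn.rasterize_phantom_ct(tree, spec)

mask, mesh, model_cloud = rn.build_ct_model(ct, kidney, seed=3)

dice = rn.dice_coefficient(mask, cs_truth)
print(f"extracted {int(mask.data.sum())} lumen voxels "
      f"(truth {int(cs_truth.data.sum())}); Dice = {dice:.4f}")
print(f"mesh: {len(mesh.vertices)} vertices, {len(mesh.faces)} faces, "
      f"area {mesh.area:.0f} mm^2")
print(f"model cloud: {len(model_cloud)} surface samples with normals")
print("-> Dice close to 1 means the three-class Otsu threshold cleanly "
      "separates contrast-filled lumen from parenchyma at this noise level; "
      "the clinical benchmark for this step is 0.853.")
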