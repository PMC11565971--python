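"""Register a synthetic annotated brain to the mini atlas.

Builds a mini label atlas, derives an experimental brain from it under a
known affine chain with per-slice alignment jitter, fits the six-step
registration chain from the annotated fiducials and bounding boxes, and
maps the annotated cells back into atlas coordinates.
"""

import numpy as np

from thalamap import ChainParams, gen_brain_from_atlas, gen_mini_atlas, map_to_atlas, register_brain

atlas = gen_mini_atlas(seed=0)
print(f"mini atlas: {atlas.shape} voxels at {atlas.voxel_um} um, "
      f"regions {', '.join(atlas.regions['name'])}")

params = ChainParams(t_ap=900.0, t_dv=-400.0, t_ml=300.0, shear=0.04,
                     ap_scale=1.12, dv_scale=0.9, ml_scale=1.05)
brain, truth = gen_brain_from_atlas(atlas, chain_params=params, n_cells=300,
                                    jitter_sd=10.0, seed=1)
print(f"synthetic brain: {brain.n_cells} annotated cells on "
      f"{len(brain.boxes)} sections, 10 um/section-plane jitter SD")

chain = register_brain(brain, atlas)
eff = chain.effective_params
print("fitted vs true (composed map):")
for key, true_val in (("ap_scale", params.ap_scale), ("dv_scale", params.dv_scale),
                      ("ml_scale", params.ml_scale), ("shear", params.shear)):
    print(f"  {key:9s} fitted {eff[key]:+.4f}  true {true_val:+.4f}")

pts = np.column_stack([
    brain.cells["section_index"] * brain.section_thickness_um,
    brain.cells["dv_um"], brain.cells["ml_um"],
])
mapped = map_to_atlas(chain, pts, section_index=brain.cells["section_index"].to_numpy())
err = np.linalg.norm(mapped - truth.cell_atlas_coords, axis=1)
print(f"cell mapping error vs ground truth: median {np.median(err):.1f} um, "
      f"95th pct {np.percentile(err, 95):.1f} um")
print("(errors well under one 10 um atlas voxel mean the inverse per-slice")
print(" chain recovers each cell's true atlas position despite the jitter)")
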