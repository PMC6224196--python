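"""Measure ligand uptake in a marked mosaic clone.

A clone covering one lateral half of cells 4-6 takes up ligand at one
quarter of the wild-type rate.  The outside/inside ratio of area-normalized
intensity densities, using a mirrored equal-area control ROI at the same
axial position, recovers the uptake deficit.
"""

import numpy as np
from scipy.ndimage import binary_erosion

import cytograd as cg

ratios = []
for seed in range(1, 11):
    config = cg.SceneConfig(
        n_cells=12, seed=seed,
        clones=[cg.CloneConfig(cell_range=(4, 6), uptake_factor=0.25)])
    stack, truth = cg.render_scene(config)
    # draw the measurement ROI interior to the clone, clear of its border
    roi = binary_erosion(truth.clone_masks[0], iterations=4)
    m = cg.clone_ratio(stack, roi, midline=cg.axis_midline(config.axis_length))
    ratios.append(m.ratio_out_in)

print("per-scene outside/inside ratios:", np.round(ratios, 2))
print(f"mean ratio = {np.mean(ratios):.2f} (expected 1/0.25 = 4.0)")
print("\nA ratio near 4 shows the clone accumulates four-fold less ligand "
      "per unit area than its wild-type neighbours - the signature of a "
      "cell-autonomous uptake defect.")
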