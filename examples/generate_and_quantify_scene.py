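"""Generate a synthetic microscopy scene and recover its gradient.

The generator renders a tubular epithelium with an exponential ligand
gradient (decay length 20 um here) as a diffuse pool plus discrete puncta;
the quantification side extracts a 40-px band profile along the axis, fits
the exponential trend and reports the Cmax-to-C-half-max slope.
"""

import cytograd as cg

config = cg.SceneConfig(n_cells=12, seed=1,
                        gradient=cg.GradientConfig(Cmax=100.0, lam=20.0))
stack, truth = cg.render_scene(config)
print(f"rendered {stack.shape[0]}x{stack.shape[1]} px scene with "
      f"{len(truth.puncta)} puncta and {len(truth.traces)} cytoneme traces")

profile = cg.extract_profile(stack, cg.axis_midline(config.axis_length),
                             channel="ligand")
fit = cg.fit_exponential(profile)
print(f"fitted decay length lambda = {fit.lam:.2f} um "
      f"(configured 20.00, error {abs(fit.lam - 20) / 20:.1%})")
print(f"Cmax = {fit.Cmax:.1f} AU, slope (Cmax to C-half-max) = "
      f"{fit.slope:.3f} AU/um, r^2 = {fit.r2:.3f}")
print("\nThe slope summarizes gradient steepness as the straight line from "
      "the profile maximum to its half-maximum point; shallow, long-range "
      "gradients have small slopes.")
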