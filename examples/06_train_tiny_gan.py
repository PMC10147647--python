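"""Train both enhancement networks at desk scale on a simulated phantom and
run the sequential NetA -> NetB inference.  Takes a couple of minutes on one
CPU; sizes are deliberately tiny."""

import numpy as np

import fringeoct as fo
from fringeoct.pipeline import TrainConfig, prepare_pairs_a, prepare_pairs_b, train

axis = fo.SpectralAxis(n_samples=256, span=1000.0, source_fwhm=661.0)
phantom = fo.PhantomSpec(depth_extent=500.0, lateral_extent=256.0,
                         layer_boundaries=[(100.0, 0.3), (300.0, 0.1)],
                         scatterer_density=3.0,
                         discrete_reflectors=[(420.0, 128.0, 1.0)], seed=17)
comp = fo.DispersionModel()
stack = fo.simulate_bscan_stack(phantom, 7, 2.0, axis, comp, noise_std=0.02,
                                n_ascans=64, seed=3)

envelope = fo.calibrate_dispersion_bound(axis)
pairs_a = prepare_pairs_a(stack, envelope, comp, n_pairs=16, seed=7)
result_a = train(pairs_a, TrainConfig(net="A", epochs=3, batch_size=8,
                                      seed=1, base_channels=6))
print("NetA generator loss per epoch:",
      [round(v, 4) for v in result_a.history["generator"]])

pairs_b = prepare_pairs_b([stack], comp, seed=9, patch=48)
result_b = train(pairs_b * 6, TrainConfig(net="B", epochs=2, batch_size=2,
                                          seed=1, base_channels=6,
                                          ms_ssim_scales=2))
print("NetB generator loss per epoch:",
      [round(v, 4) for v in result_b.history["generator"]])

enhanced = fo.enhance(stack[3], result_a.generator, result_b.generator, comp)
print(f"enhanced B-scan: shape {enhanced.shape}, "
      f"range [{enhanced.values.min():.2f}, {enhanced.values.max():.2f}]")
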