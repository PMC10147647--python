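"""Simulate raw swept-source OCT fringes of a bead phantom and reconstruct
the A-scan, checking the measured axial resolution against the source
bandwidth."""

import numpy as np

import fringeoct as fo

axis = fo.SpectralAxis()  # 1290 nm centre, 110 nm bandwidth, 2048 samples
print(f"depth pitch {axis.depth_pitch_um:.2f} um, "
      f"unambiguous range {axis.max_depth_um:.0f} um")

fringe = fo.simulate_fringe([1000.0], [1.0], axis, noise_std=0.02, seed=1)
profile = fo.reconstruct_ascan(fringe)
peak_px = int(np.argmax(profile.values[5:])) + 5
print(f"bead at 1000 um reconstructs at pixel {peak_px} "
      f"({peak_px * profile.depth_pitch_um:.1f} um)")

fwhm = fo.measure_psf_fwhm(fringe)
print(f"axial PSF width (3 dB): {fwhm:.2f} um")
# The width tracks 1/bandwidth: a Gaussian source of 661 cm^-1 FWHM gives
# ~4.7 um; sweep-edge clipping of the source tails broadens it slightly.
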