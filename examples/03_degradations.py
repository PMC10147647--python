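"""Sample and apply the two training-input degradations: imperfect
dispersion compensation plus bandwidth truncation (axial network), and
blur/SNR deterioration of B-scans (lateral network)."""

import fringeoct as fo

axis = fo.SpectralAxis()
mirror = fo.simulate_fringe([1000.0], [1.0], axis)
optimal = fo.measure_psf_fwhm(mirror)

# calibrate the dispersion-mismatch envelope so the worst case doubles the PSF
envelope = fo.calibrate_dispersion_bound(axis, target_broadening=2.0)
print(f"envelope: |da2| <= {envelope.max_abs_a2:.3e}, "
      f"|da3| <= {envelope.max_abs_a3:.3e}")

for seed in range(3):
    spec = fo.sample_degradation_a(envelope, seed)
    degraded, ascan, spect = fo.apply_degradation_a(mirror, spec)
    comp = fo.DispersionModel(-spec.delta_a2, -spec.delta_a3,
                              axis.center_wavenumber)
    ratio = fo.measure_psf_fwhm(degraded, comp) / optimal
    print(f"draw {seed}: truncation {spec.truncation_factor:.2f}, "
          f"PSF broadened {ratio:.2f}x (bounded by ~2x)")

for seed in range(3):
    spec = fo.sample_degradation_b(seed)
    print(f"B-scan degradation {seed}: truncation {spec.truncation_factor:.2f}, "
          f"filter {spec.filter_size}px sigma {spec.filter_sigma:.1f}, "
          f"{spec.snr_mode} {spec.snr_shift_db:.2f} dB")
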