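"""Degradation-sampler and ground-truth-builder tests."""

import numpy as np
import pytest

import fringeoct as fo
from fringeoct.degrade import estimate_noise_floor_db
from fringeoct.errors import InvalidSpecError


@pytest.fixture(scope="module")
def envelope_small(axis_small):
    return fo.calibrate_dispersion_bound(axis_small)


@pytest.fixture(scope="module")
def mirror_small(axis_small):
    return fo.simulate_fringe([300.0], [1.0], axis_small)


class TestCalibrateDispersionBound:
    def test_unit_target_gives_zero_envelope(self, axis_small):
        env = fo.calibrate_dispersion_bound(axis_small, target_broadening=1.0)
        assert env.max_abs_a2 == 0.0 and env.max_abs_a3 == 0.0

    def test_bound_reproduces_target_broadening(self, axis_small, envelope_small,
                                                mirror_small):
        opt = fo.measure_psf_fwhm(mirror_small)
        for comp in (fo.DispersionModel(-envelope_small.max_abs_a2, 0.0,
                                        axis_small.center_wavenumber),
                     fo.DispersionModel(0.0, -envelope_small.max_abs_a3,
                                        axis_small.center_wavenumber)):
            ratio = fo.measure_psf_fwhm(mirror_small, comp) / opt
            assert ratio == pytest.approx(2.0, abs=0.05)

    def test_envelope_is_monotone_in_target(self, axis_small, envelope_small):
        smaller = fo.calibrate_dispersion_bound(axis_small, target_broadening=1.5)
        assert smaller.max_abs_a2 < envelope_small.max_abs_a2
        assert smaller.max_abs_a3 < envelope_small.max_abs_a3


class TestSamplerA:
    def test_same_seed_gives_identical_spec(self, envelope_small):
        assert (fo.sample_degradation_a(envelope_small, 42)
                == fo.sample_degradation_a(envelope_small, 42))

    def test_truncation_factor_never_below_half(self, envelope_small):
        factors = [fo.sample_degradation_a(envelope_small, s).truncation_factor
                   for s in range(1000)]
        assert min(factors) >= 0.5
        assert max(factors) <= 1.0

    def test_broadening_bounded_by_factor_two(self, axis_small, envelope_small,
                                              mirror_small):
        """500 dispersion-only draws must stay within 2x (+5% tolerance)."""
        opt = fo.measure_psf_fwhm(mirror_small)
        worst = 0.0
        for s in range(500):
            spec = fo.sample_degradation_a(envelope_small, s)
            comp = fo.DispersionModel(-spec.delta_a2, -spec.delta_a3,
                                      axis_small.center_wavenumber)
            worst = max(worst, fo.measure_psf_fwhm(mirror_small, comp) / opt)
        assert worst <= 2.0 * 1.05


class TestApplyDegradationA:
    def test_null_spec_is_identity(self, axis_small, mirror_small):
        spec = fo.DegradationSpecA(0.0, 0.0, 1.0)
        comp = fo.DispersionModel()
        _, ascan, spect = fo.apply_degradation_a(mirror_small, spec, comp)
        assert np.allclose(ascan.values,
                           fo.reconstruct_ascan(mirror_small, comp).values)
        assert np.allclose(spect.values, fo.spectrogram(mirror_small).values)

    def test_half_truncation_doubles_psf_on_untruncated_source(self, axis_wide):
        fringe = fo.simulate_fringe([1000.0], [1.0], axis_wide)
        opt = fo.measure_psf_fwhm(fringe)
        degraded = fo.apply_truncation_window(fringe, 0.5)
        assert fo.measure_psf_fwhm(degraded) / opt == pytest.approx(2.0, rel=0.05)

    def test_reciprocity_of_width_and_effective_bandwidth(self, axis_wide):
        """PSF FWHM x effective truncated bandwidth is constant over
        truncation factors 0.5-1.0 (within 5%)."""
        fringe = fo.simulate_fringe([1000.0], [1.0], axis_wide)
        products = []
        for tf in (0.5, 0.625, 0.75, 0.875, 1.0):
            w = fo.measure_psf_fwhm(fo.apply_truncation_window(fringe, tf))
            products.append(w * tf * axis_wide.source_fwhm)
        assert max(products) / min(products) < 1.05

    def test_band_count_unchanged_by_degradation(self, axis_small, mirror_small,
                                                 envelope_small):
        for s in (0, 1, 2):
            spec = fo.sample_degradation_a(envelope_small, s)
            _, _, spect = fo.apply_degradation_a(mirror_small, spec,
                                                 fo.DispersionModel())
            assert spect.bands == fo.stft_band_count(axis_small)


class TestSamplerB:
    def test_same_seed_gives_identical_spec(self):
        assert fo.sample_degradation_b(7) == fo.sample_degradation_b(7)

    def test_bounds_over_1000_draws(self):
        specs = [fo.sample_degradation_b(s) for s in range(1000)]
        assert min(s.truncation_factor for s in specs) >= 0.8
        assert max(s.truncation_factor for s in specs) <= 1.0
        assert max(abs(s.snr_shift_db) for s in specs) <= 3.0
        assert all(s.filter_size % 2 == 1 and 5 <= s.filter_size <= 15
                   for s in specs)
        assert all(1.0 <= s.filter_sigma <= 5.0 for s in specs)
        modes = {s.snr_mode for s in specs}
        assert modes == {"attenuate_signal", "amplify_noise"}


class TestApplyDegradationB:
    def test_null_spec_matches_optimal_bscan(self, speckle_stack):
        spec = fo.DegradationSpecB(1.0, 5, 0.0, "attenuate_signal", 0.0)
        comp = fo.DispersionModel()
        degraded, window = fo.apply_degradation_b(speckle_stack[3], spec, comp)
        optimal = fo.reconstruct_bscan(speckle_stack[3], comp)
        expected = fo.normalize(optimal.values, *window)
        assert np.allclose(degraded.values, expected, atol=1e-6)

    def test_blur_is_lateral_only(self, axis_small):
        """A blurred isolated bead broadens laterally; its axial width is
        preserved within 2%."""
        bead = fo.PhantomSpec(depth_extent=500.0, lateral_extent=256.0,
                              scatterer_density=0.0,
                              discrete_reflectors=[(250.0, 128.0, 1.0)], seed=2)
        frame = fo.simulate_bscan_frame(fo.make_phantom(bead), axis_small,
                                        noise_std=0.0, n_ascans=64, seed=0)
        comp = fo.DispersionModel()
        spec = fo.DegradationSpecB(1.0, 15, 5.0, "attenuate_signal", 0.0)
        degraded, window = fo.apply_degradation_b(frame, spec, comp)
        optimal = fo.normalize(fo.reconstruct_bscan(frame, comp).values, *window)
        col = int(np.argmax(optimal.max(axis=0)))
        row = int(np.argmax(optimal[:, col]))

        def widths(img):
            ax_w = fo.measure_resolution(
                fo.denormalize(img[:, col], *window), 1.0, exclude_dc=5)
            lat_w = fo.measure_resolution(
                fo.denormalize(img[row, :], *window), 1.0)
            return ax_w, lat_w

        ax0, lat0 = widths(optimal)
        ax1, lat1 = widths(degraded.values)
        assert lat1 > lat0 * 1.5
        assert ax1 == pytest.approx(ax0, rel=0.02)

    def test_attenuation_shift_lowers_signal_by_3db(self, speckle_stack):
        comp = fo.DispersionModel()
        base = fo.DegradationSpecB(1.0, 5, 0.0, "attenuate_signal", 0.0)
        shifted = fo.DegradationSpecB(1.0, 5, 0.0, "attenuate_signal", 3.0)
        img0, window = fo.apply_degradation_b(speckle_stack[3], base, comp)
        img1, _ = fo.apply_degradation_b(speckle_stack[3], shifted, comp,
                                         normalization=window)
        db0 = fo.denormalize(img0.values, *window)
        db1 = fo.denormalize(img1.values, *window)
        floor = estimate_noise_floor_db(db0)
        mask = db0 > floor + 6.0  # solidly in the signal region
        drop = (db0[mask] - db1[mask]).mean()
        assert drop == pytest.approx(3.0, abs=0.1)

    def test_noise_amplification_raises_floor(self, speckle_stack):
        comp = fo.DispersionModel()
        spec = fo.DegradationSpecB(1.0, 5, 0.0, "amplify_noise", 3.0, seed=5)
        img, window = fo.apply_degradation_b(speckle_stack[3], spec, comp)
        optimal = fo.reconstruct_bscan(speckle_stack[3], comp)
        floor0 = estimate_noise_floor_db(optimal.values)
        floor1 = estimate_noise_floor_db(fo.denormalize(img.values, *window))
        assert floor1 > floor0 + 1.0


class TestGroundTruthB:
    def test_identical_frames_average_to_themselves(self, optimal_images):
        frames = [optimal_images[0]] * 7
        avg = fo.build_ground_truth_b(frames)
        assert np.allclose(avg.values, optimal_images[0].values)

    def test_weights_are_normalized_for_any_sigma(self):
        for sigma in (0.5, 1.5, 4.0):
            assert fo.gaussian_frame_weights(7, sigma).sum() == pytest.approx(1.0)

    def test_wrong_frame_count_rejected(self, optimal_images):
        with pytest.raises(InvalidSpecError):
            fo.build_ground_truth_b(optimal_images[:5])

    def test_speckle_contrast_drops_versus_center_frame(self, optimal_images,
                                                        axis_small):
        avg = fo.build_ground_truth_b(optimal_images)

        def contrast(image):
            pitch = axis_small.depth_pitch_um
            linear = 10.0 ** (image.values / 20.0)
            region = linear[int(110 / pitch): int(280 / pitch), 10: 50]
            return region.std() / region.mean()

        assert contrast(avg) < contrast(optimal_images[3])
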