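"""Forward-model tests: phantoms, fringes, and frame stacks."""

import numpy as np
import pytest

import fringeoct as fo
from fringeoct.errors import InvalidSpecError, OutOfRangeError

from conftest import analytic_3db_width_um


class TestMakePhantom:
    def test_empty_spec_gives_empty_field(self):
        field = fo.make_phantom(fo.PhantomSpec(scatterer_density=0.0))
        assert len(field) == 0

    def test_single_discrete_reflector(self):
        spec = fo.PhantomSpec(depth_extent=1000.0, scatterer_density=0.0,
                              discrete_reflectors=[(500.0, 0.0, 1.0)])
        field = fo.make_phantom(spec)
        assert len(field) == 1
        assert field.depths[0] == 500.0
        assert field.amplitudes[0] == 1.0 + 0.0j

    def test_same_seed_is_bitwise_identical(self, layered_phantom):
        f1 = fo.make_phantom(layered_phantom)
        f2 = fo.make_phantom(layered_phantom)
        assert np.array_equal(f1.depths, f2.depths)
        assert np.array_equal(f1.laterals, f2.laterals)
        assert np.array_equal(f1.amplitudes, f2.amplitudes)

    def test_scatterer_count_tracks_density(self):
        spec = fo.PhantomSpec(depth_extent=1000.0, lateral_extent=1300.0,
                              layer_boundaries=[(0.0, 0.5)],
                              scatterer_density=4.0, seed=5)
        n_cells = (1000.0 / spec.axial_cell_um) * (1300.0 / spec.lateral_cell_um)
        n = len(fo.make_phantom(spec))
        expected = 4.0 * n_cells
        assert abs(n - expected) < 5.0 * np.sqrt(expected)  # Poisson spread

    def test_negative_density_rejected(self):
        with pytest.raises(InvalidSpecError):
            fo.PhantomSpec(scatterer_density=-1.0)

    def test_negative_extent_rejected(self):
        with pytest.raises(InvalidSpecError):
            fo.PhantomSpec(depth_extent=-5.0)


class TestSimulateFringe:
    def test_empty_column_reduces_to_background(self, axis_default):
        f = fo.simulate_fringe([], [], axis_default, noise_std=0.0)
        assert np.array_equal(f.samples, f.background)

    def test_peak_bin_maps_to_depth(self, axis_default):
        f = fo.simulate_fringe([1000.0], [1.0], axis_default)
        profile = fo.reconstruct_ascan(f)
        peak = int(np.argmax(profile.values[5:])) + 5
        assert peak == round(1000.0 / profile.depth_pitch_um)

    def test_psf_fwhm_matches_gaussian_closed_form(self, axis_wide):
        f = fo.simulate_fringe([1000.0], [1.0], axis_wide)
        measured = fo.measure_psf_fwhm(f)
        expected = analytic_3db_width_um(axis_wide.source_fwhm)
        assert measured == pytest.approx(expected, rel=0.05)

    def test_peak_magnitude_ratio_is_linear(self, axis_default):
        f = fo.simulate_fringe([800.0, 3000.0], [1.0, 0.5], axis_default)
        profile = fo.reconstruct_ascan(f)
        linear = 10.0 ** (profile.values / 20.0)
        i1 = round(800.0 / profile.depth_pitch_um)
        i2 = round(3000.0 / profile.depth_pitch_um)
        p1 = linear[i1 - 4: i1 + 5].max()
        p2 = linear[i2 - 4: i2 + 5].max()
        assert p1 / p2 == pytest.approx(2.0, rel=0.05)

    def test_fringe_superposition_is_linear(self, axis_default):
        f12 = fo.simulate_fringe([700.0, 1500.0], [1.0, 0.8], axis_default)
        f1 = fo.simulate_fringe([700.0], [1.0], axis_default)
        f2 = fo.simulate_fringe([1500.0], [0.8], axis_default)
        combined = f1.samples + f2.samples - f1.background
        assert np.allclose(f12.samples, combined, atol=1e-9)

    def test_halved_bandwidth_doubles_psf(self, axis_wide):
        narrow = fo.SpectralAxis(axis_wide.n_samples, axis_wide.center_wavenumber,
                                 axis_wide.span, axis_wide.source_fwhm / 2.0)
        w_full = fo.measure_psf_fwhm(fo.simulate_fringe([1000.0], [1.0], axis_wide))
        w_half = fo.measure_psf_fwhm(fo.simulate_fringe([1000.0], [1.0], narrow))
        assert w_half / w_full == pytest.approx(2.0, rel=0.05)

    def test_reflector_beyond_range_rejected(self, axis_default):
        with pytest.raises(OutOfRangeError):
            fo.simulate_fringe([axis_default.max_depth_um + 1.0], [1.0],
                               axis_default)

    def test_noise_is_seed_deterministic(self, axis_small):
        f1 = fo.simulate_fringe([100.0], [1.0], axis_small, noise_std=0.1, seed=9)
        f2 = fo.simulate_fringe([100.0], [1.0], axis_small, noise_std=0.1, seed=9)
        assert np.array_equal(f1.samples, f2.samples)


class TestBScanStack:
    def test_single_frame_equals_direct_simulation(self, layered_phantom, axis_small):
        stack = fo.simulate_bscan_stack(layered_phantom, 1, 2.0, axis_small,
                                        noise_std=0.0, n_ascans=8, seed=4)
        field = fo.make_phantom(layered_phantom)
        direct = fo.simulate_bscan_frame(field, axis_small, noise_std=0.0,
                                         n_ascans=8, seed=0)
        assert len(stack) == 1
        for a, b in zip(stack[0], direct):
            assert np.allclose(a.samples, b.samples)

    def test_zero_interval_gives_identical_frames(self, layered_phantom, axis_small):
        stack = fo.simulate_bscan_stack(layered_phantom, 3, 0.0, axis_small,
                                        noise_std=0.0, n_ascans=8, seed=4)
        for frame in stack[1:]:
            for a, b in zip(stack[0], frame):
                assert np.array_equal(a.samples, b.samples)

    def test_speckle_correlation_decreases_with_separation(self, optimal_images):
        linear = [10.0 ** (im.values / 20.0) for im in optimal_images]
        by_sep = {}
        for a in range(len(linear)):
            for b in range(a + 1, len(linear)):
                corr = np.corrcoef(linear[a].ravel(), linear[b].ravel())[0, 1]
                by_sep.setdefault(b - a, []).append(corr)
        means = [np.mean(by_sep[d]) for d in sorted(by_sep)]
        assert all(x > y for x, y in zip(means, means[1:]))

    def test_negative_interval_rejected(self, layered_phantom, axis_small):
        with pytest.raises(InvalidSpecError):
            fo.simulate_bscan_stack(layered_phantom, 2, -1.0, axis_small)

    def test_hdf5_round_trip(self, tmp_path, layered_phantom, axis_small):
        stack = fo.simulate_bscan_stack(layered_phantom, 2, 2.0, axis_small,
                                        noise_std=0.01, n_ascans=8, seed=4)
        path = tmp_path / "stack.h5"
        fo.save_fringes_h5(path, stack, layered_phantom)
        loaded, disp = fo.load_fringes_h5(path)
        assert len(loaded) == 2 and len(loaded[0]) == 8
        assert np.allclose(loaded[0][0].samples, stack[0][0].samples,
                           atol=1e-4)  # float32 storage
        assert loaded[0][0].axis.n_samples == axis_small.n_samples
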