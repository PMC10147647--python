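"""Shared fixtures: spectral axes, phantoms and simulated frame stacks.

Everything is generated programmatically at session scope so expensive
simulations are shared across test modules.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fringeoct as fo

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@pytest.fixture(scope="session")
def axis_default() -> fo.SpectralAxis:
    """The study axis: 2048 samples, 1000 cm^-1 span, 661 cm^-1 FWHM."""
    return fo.SpectralAxis()


@pytest.fixture(scope="session")
def axis_wide() -> fo.SpectralAxis:
    """Axis whose span comfortably contains the source envelope, so the
    Gaussian Fourier-pair closed forms hold to high accuracy."""
    return fo.SpectralAxis(n_samples=2048, span=2800.0, source_fwhm=661.0)


@pytest.fixture(scope="session")
def axis_small() -> fo.SpectralAxis:
    """Desk-scale axis (256 samples) keeping the 1000 cm^-1 span."""
    return fo.SpectralAxis(n_samples=256, span=1000.0, source_fwhm=661.0)


def analytic_3db_width_um(source_fwhm_cm1: float) -> float:
    """Closed-form 3 dB log-amplitude PSF width in depth for a Gaussian
    source of the given spectral FWHM (fringe phase 2*pi*(2z)*k)."""
    sigma_k = source_fwhm_cm1 * FWHM_TO_SIGMA
    sigma_x = 1.0 / (2.0 * np.pi * sigma_k)           # cm, in x = 2z
    half_x = sigma_x * np.sqrt(2.0 * np.log(10.0 ** (3.0 / 20.0)))
    return half_x * 1.0e4                              # full width in z (um)


@pytest.fixture(scope="session")
def layered_phantom() -> fo.PhantomSpec:
    return fo.PhantomSpec(
        depth_extent=500.0, lateral_extent=256.0,
        layer_boundaries=[(100.0, 0.3), (300.0, 0.1)],
        scatterer_density=3.0,
        discrete_reflectors=[(420.0, 128.0, 1.0)],
        seed=17)


@pytest.fixture(scope="session")
def speckle_stack(layered_phantom, axis_small):
    """7 adjacent frames at 2 um interval, 64 A-scans each."""
    return fo.simulate_bscan_stack(layered_phantom, 7, 2.0, axis_small,
                                   noise_std=0.02, n_ascans=64, seed=3)


@pytest.fixture(scope="session")
def optimal_images(speckle_stack):
    comp = fo.DispersionModel()
    return [fo.reconstruct_bscan(frame, comp) for frame in speckle_stack]
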