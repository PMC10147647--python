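"""Input-degradation samplers and the multi-frame ground-truth builder.

Training pairs for the two enhancement networks are made by degrading the
optimally reconstructed data:

* NetA (axial): imperfect numerical dispersion compensation (random
  perturbation of the polynomial phase coefficients, calibrated so the
  axial PSF broadens by at most a factor of 2) and bandwidth truncation
  (Gaussian spectral window narrowing the effective bandwidth to a factor
  drawn uniformly in [0.5, 1]).
* NetB (lateral/speckle): mild bandwidth truncation ([0.8, 1]), lateral-only
  Gaussian blurring (size 5-15 px, sigma 1-5), and SNR deterioration of up
  to 3 dB, either by attenuating the signal or amplifying the noise floor.

The NetB ground truth is the Gaussian-weighted average of 7 adjacent
optimally reconstructed B-scans (~2 um frame interval), which suppresses
speckle while preserving structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, InvalidSpecError
from .recon import (AScanProfile, BScanImage, SpectrogramTensor,
                    default_normalization_window, measure_psf_fwhm, normalize,
                    reconstruct_ascan, reconstruct_bscan, spectrogram)
from .simulate import DispersionModel, FringeRecord, SpectralAxis, simulate_fringe

__all__ = [
    "DegradationSpecA",
    "DegradationSpecB",
    "DispersionEnvelope",
    "calibrate_dispersion_bound",
    "sample_degradation_a",
    "apply_truncation_window",
    "apply_degradation_a",
    "sample_degradation_b",
    "apply_degradation_b",
    "build_ground_truth_b",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class DegradationSpecA:
    """Sampled degradation for one NetA training fringe."""

    delta_a2: float
    delta_a3: float
    truncation_factor: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 <= self.truncation_factor <= 1.0):
            raise InvalidSpecError("truncation_factor must lie in [0.5, 1]")


@dataclass(frozen=True)
class DegradationSpecB:
    """Sampled degradation for one NetB training B-scan."""

    truncation_factor: float
    filter_size: int
    filter_sigma: float
    snr_mode: str  # "attenuate_signal" | "amplify_noise"
    snr_shift_db: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.8 <= self.truncation_factor <= 1.0):
            raise InvalidSpecError("truncation_factor must lie in [0.8, 1]")
        if self.filter_size % 2 == 0 or not (5 <= self.filter_size <= 15):
            raise InvalidSpecError("filter_size must be odd and in [5, 15]")
        if not (0.0 <= self.filter_sigma <= 5.0):
            raise InvalidSpecError("filter_sigma must lie in [0, 5]")
        if self.snr_mode not in ("attenuate_signal", "amplify_noise"):
            raise InvalidSpecError("unknown snr_mode")
        if not (0.0 <= self.snr_shift_db <= 3.0):
            raise InvalidSpecError("snr_shift_db must lie in [0, 3]")


@dataclass(frozen=True)
class DispersionEnvelope:
    """Calibrated per-coefficient perturbation bounds."""

    max_abs_a2: float
    max_abs_a3: float
    target_broadening: float
    axis: SpectralAxis


def _mirror_fringe(axis: SpectralAxis, depth_um: float | None = None) -> FringeRecord:
    if depth_um is None:
        depth_um = axis.max_depth_um * 0.2
    return simulate_fringe([depth_um], [1.0], axis)


def _broadening(axis: SpectralAxis, delta_a2: float, delta_a3: float,
                fringe: FringeRecord | None = None,
                optimal_fwhm: float | None = None) -> float:
    """Measured PSF FWHM ratio caused by a compensation mismatch."""
    if fringe is None:
        fringe = _mirror_fringe(axis)
    if optimal_fwhm is None:
        optimal_fwhm = measure_psf_fwhm(fringe)
    mismatch = DispersionModel(-delta_a2, -delta_a3,
                               axis.center_wavenumber)
    return measure_psf_fwhm(fringe, mismatch) / optimal_fwhm


def calibrate_dispersion_bound(axis: SpectralAxis,
                               target_broadening: float = 2.0,
                               tol: float = 1.0e-3,
                               max_iter: int = 100) -> DispersionEnvelope:
    """Find per-coefficient bounds that broaden the axial PSF by the target.

    For each coefficient (the other held at zero) the bound is located by
    bracketing + bisection on the measured mirror-PSF FWHM ratio.  The
    sampler scales joint draws so combined perturbations stay within the
    target (see :func:`sample_degradation_a`).
    """
    if target_broadening < 1.0:
        raise InvalidSpecError("target_broadening must be >= 1")
    fringe = _mirror_fringe(axis)
    opt = measure_psf_fwhm(fringe)
    if target_broadening == 1.0:
        return DispersionEnvelope(0.0, 0.0, 1.0, axis)
    sigma_k = axis.source_fwhm * _FWHM_TO_SIGMA
    bounds = []
    # characteristic scales from the Gaussian chirp closed form
    for scale, which in ((1.0 / (2.0 * sigma_k**2), "a2"),
                         (1.0 / (6.0 * sigma_k**3), "a3")):
        lo, hi = 0.0, scale
        it = 0
        while _broadening(axis, *(hi, 0.0) if which == "a2" else (0.0, hi),
                          fringe=fringe, optimal_fwhm=opt) < target_broadening:
            hi *= 2.0
            it += 1
            if it > max_iter:
                raise CalibrationError("failed to bracket the broadening target")
        for it in range(max_iter):
            mid = 0.5 * (lo + hi)
            args = (mid, 0.0) if which == "a2" else (0.0, mid)
            if _broadening(axis, *args, fringe=fringe, optimal_fwhm=opt) < target_broadening:
                lo = mid
            else:
                hi = mid
            if (hi - lo) < tol * hi:
                break
        else:
            raise CalibrationError("bisection did not converge")
        bounds.append(0.5 * (lo + hi))
    return DispersionEnvelope(bounds[0], bounds[1], target_broadening, axis)


def sample_degradation_a(envelope: DispersionEnvelope, seed: int) -> DegradationSpecA:
    """Draw one NetA degradation spec, reproducible by seed.

    Coefficient perturbations are drawn uniformly within the calibrated
    box and then shrunk onto the L1 simplex (|u2| + |u3| <= 1 in units of
    the per-coefficient bounds) so that joint draws never exceed the
    calibrated broadening target; the truncation factor is uniform in
    [0.5, 1].
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDE6A01]))
    u2 = rng.uniform(-1.0, 1.0)
    u3 = rng.uniform(-1.0, 1.0)
    norm = abs(u2) + abs(u3)
    if norm > 1.0:
        u2, u3 = u2 / norm, u3 / norm
    tf = rng.uniform(0.5, 1.0)
    return DegradationSpecA(u2 * envelope.max_abs_a2, u3 * envelope.max_abs_a3,
                            tf, seed)


def apply_truncation_window(fringe: FringeRecord,
                            truncation_factor: float) -> FringeRecord:
    """Narrow the effective source bandwidth to ``truncation_factor`` x original.

    The Gaussian window sigma is chosen so the product of window and source
    envelope has exactly ``truncation_factor`` times the source bandwidth,
    making the axial PSF broaden reciprocally (1/factor).  A factor of 1 is
    the identity.
    """
    if not (0.0 < truncation_factor <= 1.0):
        raise InvalidSpecError("truncation_factor must lie in (0, 1]")
    if truncation_factor == 1.0:
        return FringeRecord(fringe.samples.copy(), fringe.background.copy(),
                            fringe.axis, fringe.dispersion)
    axis = fringe.axis
    sigma_s = axis.source_fwhm * _FWHM_TO_SIGMA
    sigma_w = sigma_s * truncation_factor / np.sqrt(1.0 - truncation_factor**2)
    k = axis.wavenumbers - axis.center_wavenumber
    w = np.exp(-0.5 * (k / sigma_w) ** 2)
    signal = (fringe.samples - fringe.background) * w
    return FringeRecord(fringe.background + signal, fringe.background.copy(),
                        axis, fringe.dispersion)


def apply_degradation_a(fringe: FringeRecord, spec: DegradationSpecA,
                        compensation: DispersionModel | None = None
                        ) -> tuple[FringeRecord, AScanProfile, SpectrogramTensor]:
    """Degrade one fringe for NetA: imperfect compensation + truncation.

    Returns the degraded fringe, its A-scan reconstructed with the
    perturbed compensation, and its spectrogram.  A null spec
    (0, 0, 1.0) reproduces the optimal pipeline outputs exactly.
    """
    if compensation is None:
        compensation = fringe.dispersion
    degraded = apply_truncation_window(fringe, spec.truncation_factor)
    perturbed = compensation.perturbed(spec.delta_a2, spec.delta_a3)
    ascan = reconstruct_ascan(degraded, perturbed)
    spect = spectrogram(degraded)
    return degraded, ascan, spect


def sample_degradation_b(seed: int) -> DegradationSpecB:
    """Draw one NetB degradation spec, reproducible by seed.

    Truncation factor uniform in [0.8, 1], odd filter size uniform in
    {5, 7, ..., 15}, filter sigma uniform in [1, 5], SNR mode a fair coin,
    shift uniform in [0, 3] dB.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDE6B02]))
    tf = rng.uniform(0.8, 1.0)
    size = int(rng.choice(np.arange(5, 16, 2)))
    sigma = rng.uniform(1.0, 5.0)
    mode = "attenuate_signal" if rng.random() < 0.5 else "amplify_noise"
    shift = rng.uniform(0.0, 3.0)
    return DegradationSpecB(tf, size, sigma, mode, shift, seed)


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    if sigma <= 0:
        k = np.zeros(size)
        k[size // 2] = 1.0
        return k
    x = np.arange(size) - size // 2
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _lateral_gaussian_filter(values: np.ndarray, size: int, sigma: float) -> np.ndarray:
    """Blur along the lateral (second) axis only, edge-replicated."""
    kernel = _gaussian_kernel(size, sigma)
    pad = size // 2
    padded = np.pad(values, ((0, 0), (pad, pad)), mode="edge")
    out = np.zeros_like(values)
    for i, w in enumerate(kernel):
        out += w * padded[:, i: i + values.shape[1]]
    return out


def estimate_noise_floor_db(values_db: np.ndarray, percentile: float = 25.0) -> float:
    """Noise-floor estimate: a low percentile of the dB image."""
    return float(np.percentile(values_db, percentile))


def apply_degradation_b(frame: list[FringeRecord], spec: DegradationSpecB,
                        compensation: DispersionModel | None = None,
                        normalization: tuple[float, float] | None = None
                        ) -> tuple[BScanImage, tuple[float, float]]:
    """Degrade one frame for NetB.

    Order fixed as: bandwidth truncation on the fringes -> reconstruction ->
    lateral-only Gaussian blur -> SNR deterioration in dB -> normalization
    to [-1, 1].  Returns the degraded, normalized image and the (floor,
    ceil) window used (so the paired ground truth can share it).
    """
    if compensation is None:
        compensation = frame[0].dispersion
    truncated = [apply_truncation_window(f, spec.truncation_factor) for f in frame]
    bscan = reconstruct_bscan(truncated, compensation)
    # blur the linear amplitude (a wider illumination spot adds field
    # amplitudes), then re-compress; identity when sigma -> 0
    linear = 10.0 ** (bscan.values / 20.0)
    blurred = _lateral_gaussian_filter(linear, spec.filter_size,
                                       spec.filter_sigma)
    values = 20.0 * np.log10(np.maximum(blurred, 1e-300))
    if spec.snr_shift_db > 0:
        floor_db = estimate_noise_floor_db(values)
        if spec.snr_mode == "attenuate_signal":
            above = values > floor_db
            values = np.where(above,
                              np.maximum(values - spec.snr_shift_db, floor_db),
                              values)
        else:  # amplify_noise: raise the noise floor by the drawn dB
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA271]))
            floor_amp = 10.0 ** (floor_db / 20.0)
            target_amp = 10.0 ** ((floor_db + spec.snr_shift_db) / 20.0)
            add_std = np.sqrt(max(target_amp**2 - floor_amp**2, 0.0))
            linear = 10.0 ** (values / 20.0)
            noisy = np.abs(linear + rng.normal(0.0, add_std, values.shape))
            values = 20.0 * np.log10(np.maximum(noisy, 1e-300))
    if normalization is None:
        normalization = default_normalization_window(bscan.values)
    out = normalize(values, *normalization)
    return (BScanImage(out, bscan.pixel_pitch_um, normalized=True),
            normalization)


def build_ground_truth_b(stack: list[BScanImage],
                         weight_sigma: float = 1.5,
                         n_frames: int = 7) -> BScanImage:
    """Gaussian-weighted average of adjacent optimal B-scans.

    Weights are a Gaussian over frame offset centred on the middle frame
    (sigma in frames, default 1.5 so edge frames carry ~10% of the centre
    weight), normalized to sum to one; the pixelwise weighted mean
    suppresses speckle because adjacent out-of-plane frames carry
    decorrelated speckle but (nearly) identical structure.
    """
    if len(stack) != n_frames:
        raise InvalidSpecError(f"expected {n_frames} frames, got {len(stack)}")
    shapes = {im.shape for im in stack}
    if len(shapes) != 1:
        raise InvalidSpecError("all frames must share one shape")
    offsets = np.arange(n_frames) - n_frames // 2
    w = np.exp(-0.5 * (offsets / weight_sigma) ** 2)
    w = w / w.sum()
    values = sum(wi * im.values for wi, im in zip(w, stack))
    return BScanImage(values, stack[0].pixel_pitch_um,
                      normalized=all(im.normalized for im in stack))


def gaussian_frame_weights(n_frames: int = 7, weight_sigma: float = 1.5) -> np.ndarray:
    """The normalized frame weights used by :func:`build_ground_truth_b`."""
    offsets = np.arange(n_frames) - n_frames // 2
    w = np.exp(-0.5 * (offsets / weight_sigma) ** 2)
    return w / w.sum()
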