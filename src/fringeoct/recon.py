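"""Reconstruction of A-scans, B-scans and STFT spectrograms from fringes.

The "currently optimized" chain mirrors standard swept-source OCT
post-processing: background removal, k-linearization (identity here because
the simulator emits linear-in-k samples; a resampling table hook is kept for
real, non-linear axes), numerical dispersion compensation applied as a phase
on the analytic signal, FFT with 2x zero padding, log compression, and
[-1, 1] normalization.

The spectrogram representation slices the fringe into overlapping spectral
windows (Hann-weighted), Fourier-transforms each, and stacks the resulting
depth profiles: a 2-D (band x depth) view that retains depth-dependent
spectral information lost by the plain FFT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .errors import ConfigurationError, InvalidSpecError, MeasurementError
from .simulate import DispersionModel, FringeRecord, SpectralAxis

__all__ = [
    "AScanProfile",
    "SpectrogramTensor",
    "BScanImage",
    "reconstruct_ascan",
    "reconstruct_bscan",
    "spectrogram",
    "normalize",
    "denormalize",
    "to_uint8",
    "measure_resolution",
    "measure_psf_fwhm",
    "write_tiff",
    "write_png",
    "LOG_FLOOR_RATIO",
    "DC_EXCLUDE_PX",
]

LOG_FLOOR_RATIO = 1.0e-6   # amplitudes clamped at this fraction of the max
DC_EXCLUDE_PX = 5          # depth pixels excluded from peak searches


@dataclass
class AScanProfile:
    """Single depth profile in log-amplitude (dB-like, 20*log10) units."""

    values: np.ndarray
    depth_pitch_um: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidSpecError("A-scan values must be 1-D")
        if self.normalized and (self.values.min() < -1 - 1e-9
                                or self.values.max() > 1 + 1e-9):
            raise InvalidSpecError("normalized A-scan must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SpectrogramTensor:
    """STFT of one fringe: (bands, depth) log-amplitude array."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidSpecError("spectrogram must be 2-D (bands, depth)")

    @property
    def bands(self) -> int:
        return self.values.shape[0]

    @property
    def depth(self) -> int:
        return self.values.shape[1]


@dataclass
class BScanImage:
    """Cross-sectional image, depth x lateral, log-amplitude."""

    values: np.ndarray
    pixel_pitch_um: tuple[float, float] = (2.5, 2.0)  # (axial, lateral)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidSpecError("B-scan must be 2-D (depth, lateral)")
        if self.normalized and (self.values.min() < -1 - 1e-9
                                or self.values.max() > 1 + 1e-9):
            raise InvalidSpecError("normalized B-scan must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _analytic_compensated(fringe: FringeRecord,
                          compensation: DispersionModel | None,
                          resampling_table: np.ndarray | None = None) -> np.ndarray:
    """Background-subtracted analytic signal with compensation phase removed."""
    sig = fringe.samples - fringe.background
    if resampling_table is not None:
        # hook for non-linear-in-k acquisitions: interpolate onto a uniform grid
        idx = np.arange(fringe.axis.n_samples)
        sig = np.interp(idx, resampling_table, sig)
    analytic = hilbert(sig)
    if compensation is not None:
        analytic = analytic * np.exp(-1j * compensation.phase(fringe.axis))
    return analytic


def _log_compress(mag: np.ndarray) -> np.ndarray:
    peak = mag.max()
    if peak <= 0:
        peak = 1.0
    return 20.0 * np.log10(np.maximum(mag, LOG_FLOOR_RATIO * peak))


def reconstruct_ascan(fringe: FringeRecord,
                      compensation: DispersionModel | None = None,
                      resampling_table: np.ndarray | None = None,
                      pad_factor: int = 2) -> AScanProfile:
    """Reconstruct one A-scan from a fringe.

    Background is subtracted, the compensation phase -phi(k) is applied in
    the analytic (Hilbert) representation, the signal is FFT'd at
    ``pad_factor`` x zero padding and the positive-depth half magnitude is
    log-compressed (20*log10, clamped at ``LOG_FLOOR_RATIO`` of the peak).
    An all-zero fringe yields a flat profile at the log floor.
    """
    axis = fringe.axis
    analytic = _analytic_compensated(fringe, compensation, resampling_table)
    n_fft = pad_factor * axis.n_samples
    spectrum = np.fft.fft(analytic, n=n_fft)
    half = spectrum[: n_fft // 2]
    values = _log_compress(np.abs(half))
    pitch = axis.depth_pitch_um * (axis.fft_length / n_fft)
    return AScanProfile(values, pitch)


def reconstruct_bscan(frame: list[FringeRecord],
                      compensation: DispersionModel | None = None,
                      lateral_pitch_um: float | None = None) -> BScanImage:
    """Reconstruct a B-scan (depth x lateral) from a frame of fringes.

    Log compression is applied jointly so a single floor/scale serves the
    whole image.
    """
    axis = frame[0].axis
    n_fft = axis.fft_length
    cols = np.empty((n_fft // 2, len(frame)))
    for i, fr in enumerate(frame):
        analytic = _analytic_compensated(fr, compensation)
        cols[:, i] = np.abs(np.fft.fft(analytic, n=n_fft)[: n_fft // 2])
    values = _log_compress(cols)
    if lateral_pitch_um is None:
        lateral_pitch_um = 2.0
    return BScanImage(values, (axis.depth_pitch_um, lateral_pitch_um))


def stft_band_count(axis: SpectralAxis, window_width: float = 325.0,
                    overlap: float = 275.0) -> int:
    """Number of STFT bands for the given spectral window/overlap (cm^-1)."""
    if window_width > axis.span:
        raise ConfigurationError("window_width exceeds the axis span")
    if overlap >= window_width:
        raise ConfigurationError("overlap must be smaller than window_width")
    win = int(round(window_width / axis.dk))
    ov = int(round(overlap / axis.dk))
    hop = win - ov
    if hop < 1:
        raise ConfigurationError("STFT hop rounds to zero samples")
    if win < 2 or win > axis.n_samples:
        raise ConfigurationError("STFT window rounds to an unusable size")
    return (axis.n_samples - win) // hop + 1


def spectrogram(fringe: FringeRecord, window_width: float = 325.0,
                overlap: float = 275.0) -> SpectrogramTensor:
    """Short-time Fourier transform of a fringe along the wavenumber axis.

    The window and overlap are given in cm^-1 (defaults 325 and 275, which
    yield 14 bands on the default 1000 cm^-1 axis), converted to sample
    counts by rounding.  Each Hann-windowed segment is zero padded to the
    common FFT length so every band shares the full depth grid.
    """
    axis = fringe.axis
    n_bands = stft_band_count(axis, window_width, overlap)
    win = int(round(window_width / axis.dk))
    ov = int(round(overlap / axis.dk))
    hop = win - ov
    sig = fringe.samples - fringe.background
    n_fft = axis.fft_length
    taper = np.hanning(win)
    bands = np.empty((n_bands, n_fft // 2))
    for b in range(n_bands):
        seg = sig[b * hop: b * hop + win] * taper
        mag = np.abs(np.fft.fft(seg, n=n_fft)[: n_fft // 2])
        bands[b] = mag
    return SpectrogramTensor(_log_compress(bands))


def normalize(values: np.ndarray, floor_db: float, ceil_db: float) -> np.ndarray:
    """Affine map of [floor_db, ceil_db] onto [-1, 1], clipping outside."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise InvalidSpecError("cannot normalize non-finite values")
    if not (ceil_db > floor_db):
        raise InvalidSpecError("ceil_db must exceed floor_db")
    out = 2.0 * (values - floor_db) / (ceil_db - floor_db) - 1.0
    return np.clip(out, -1.0, 1.0)


def denormalize(values: np.ndarray, floor_db: float, ceil_db: float) -> np.ndarray:
    """Inverse of :func:`normalize` on the clipped range."""
    values = np.asarray(values, dtype=float)
    return (values + 1.0) * (ceil_db - floor_db) / 2.0 + floor_db


def default_normalization_window(optimal_db: np.ndarray) -> tuple[float, float]:
    """(floor, ceil) = (5th percentile, max) of the optimal image."""
    return float(np.percentile(optimal_db, 5.0)), float(optimal_db.max())


def to_uint8(image: BScanImage | np.ndarray,
             display_range_db: tuple[float, float]) -> np.ndarray:
    """Map a dB window linearly onto 0..255 with clipping.

    Rounding is half-away-from-zero so the exact window midpoint maps to 128.
    """
    lo, hi = display_range_db
    if not (hi > lo):
        raise InvalidSpecError("display range must have hi > lo")
    values = image.values if isinstance(image, BScanImage) else np.asarray(image)
    scaled = np.clip((values - lo) / (hi - lo), 0.0, 1.0) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def measure_resolution(profile: np.ndarray, pixel_pitch_um: float,
                       exclude_dc: int = 0) -> float:
    """Full width at 3 dB below the peak of a log-amplitude profile, in um.

    The two crossings of (peak - 3 dB) are located by linear interpolation
    on either side of the global maximum.  Raises
    :class:`MeasurementError` when a crossing is missing on either side.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or len(p) < 3:
        raise MeasurementError("profile too short")
    search = p[exclude_dc:]
    ipk = int(np.argmax(search)) + exclude_dc
    if ipk <= 0 or ipk >= len(p) - 1:
        raise MeasurementError("peak at profile edge")
    thr = p[ipk] - 3.0
    # walk left
    i = ipk
    while i > 0 and p[i - 1] > thr:
        i -= 1
    if i == 0 and p[0] > thr:
        raise MeasurementError("no left 3 dB crossing")
    left = (i - 1) + (thr - p[i - 1]) / (p[i] - p[i - 1]) if i > 0 else 0.0
    # walk right
    j = ipk
    while j < len(p) - 1 and p[j + 1] > thr:
        j += 1
    if j == len(p) - 1 and p[-1] > thr:
        raise MeasurementError("no right 3 dB crossing")
    right = j + (p[j] - thr) / (p[j] - p[j + 1]) if j < len(p) - 1 else float(len(p) - 1)
    return (right - left) * pixel_pitch_um


def measure_psf_fwhm(fringe: FringeRecord,
                     compensation: DispersionModel | None = None,
                     pad_factor: int = 16) -> float:
    """Axial PSF width (um) of a reflector fringe, finely sampled.

    Reconstruction at high zero-padding samples the point-spread function
    densely enough for sub-pixel 3 dB width interpolation; used by the
    dispersion-bound calibration and resolution tests.
    """
    prof = reconstruct_ascan(fringe, compensation, pad_factor=pad_factor)
    exclude = DC_EXCLUDE_PX * pad_factor // 2
    return measure_resolution(prof.values, prof.depth_pitch_um, exclude_dc=exclude)


def write_tiff(path, image: BScanImage) -> None:
    import tifffile

    tifffile.imwrite(path, image.values.astype(np.float32))


def write_png(path, image: BScanImage, display_range_db: tuple[float, float]) -> None:
    from PIL import Image

    Image.fromarray(to_uint8(image, display_range_db), mode="L").save(path)
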