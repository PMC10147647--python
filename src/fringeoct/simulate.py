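"""Swept-source OCT fringe simulation.

A swept-source OCT interferometer records, for every lateral beam position,
a real-valued spectral interferogram ("fringe") sampled uniformly in
wavenumber k.  A reflector at optical depth z modulates the source spectrum
with a cosine of spatial frequency 2z (the round-trip path difference), so
the Fourier transform of the fringe along k yields the depth reflectivity
profile (A-scan).  This module synthesises such fringes from explicit
scatterer fields: discrete reflectors (mirrors, beads) and dense clouds of
random-phase sub-resolution scatterers, which is what produces fully
developed speckle after reconstruction.

Conventions
-----------
* wavenumber k is expressed in cm^-1 (1/lambda), depths in micrometres;
* the interferometric phase of a scatterer at depth z is 2*pi*(2*z)*k plus
  an optional polynomial dispersion phase a2*(k-k0)^2 + a3*(k-k0)^3;
* the source envelope is Gaussian with a stated FWHM in cm^-1.

The default axis matches a 1290 nm centre wavelength, 110 nm bandwidth
source: centre 10^7/1290 = 7752 cm^-1, source FWHM 10^7 * 110 / 1290^2 =
661 cm^-1, sampled over a 1000 cm^-1 span with 2048 samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np

from .errors import InvalidSpecError, OutOfRangeError

__all__ = [
    "SpectralAxis",
    "DispersionModel",
    "PhantomSpec",
    "ScattererField",
    "FringeRecord",
    "default_axis",
    "make_phantom",
    "simulate_fringe",
    "simulate_bscan_frame",
    "simulate_bscan_stack",
    "save_fringes_h5",
    "load_fringes_h5",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM * this


@dataclass(frozen=True)
class SpectralAxis:
    """Uniform (linear-in-k) wavenumber sampling grid of the swept source.

    Parameters
    ----------
    n_samples : number of spectral samples per fringe.
    center_wavenumber : cm^-1, centre of the sampled span.
    span : cm^-1, total sampled spectral extent.
    source_fwhm : cm^-1, FWHM of the Gaussian source power envelope.
    """

    n_samples: int = 2048
    center_wavenumber: float = 1.0e7 / 1290.0
    span: float = 1000.0
    source_fwhm: float = 1.0e7 * 110.0 / 1290.0**2

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise InvalidSpecError("n_samples must be >= 2")
        if self.span <= 0:
            raise InvalidSpecError("span must be positive")
        if not (0 < self.source_fwhm < self.span):
            raise InvalidSpecError("source_fwhm must lie in (0, span)")

    @property
    def dk(self) -> float:
        """Sample spacing in cm^-1."""
        return self.span / self.n_samples

    @property
    def wavenumbers(self) -> np.ndarray:
        k0 = self.center_wavenumber - self.span / 2.0
        return k0 + self.dk * np.arange(self.n_samples)

    @property
    def fft_length(self) -> int:
        """FFT length used by the reconstruction chain (2x zero padding)."""
        return 2 * self.n_samples

    @property
    def depth_pitch_um(self) -> float:
        """Depth per reconstructed pixel: the FFT bin spacing is
        1/(fft_length*dk) in optical path difference x = 2z (cm)."""
        return 1.0e4 / (2.0 * self.fft_length * self.dk)

    @property
    def max_depth_um(self) -> float:
        """Unambiguous single-sided depth range (Nyquist of the real fringe)."""
        return (self.fft_length // 2) * self.depth_pitch_um

    def source_envelope(self) -> np.ndarray:
        sigma = self.source_fwhm * _FWHM_TO_SIGMA
        k = self.wavenumbers - self.center_wavenumber
        return np.exp(-0.5 * (k / sigma) ** 2)


def default_axis() -> SpectralAxis:
    return SpectralAxis()


@dataclass(frozen=True)
class DispersionModel:
    """Polynomial dispersion phase phi(k) = a2*(k-k_ref)^2 + a3*(k-k_ref)^3.

    a2 is the group-velocity-dispersion term in rad/(cm^-1)^2, a3 the
    third-order term in rad/(cm^-1)^3.  Zero coefficients mean a perfectly
    balanced interferometer.
    """

    a2: float = 0.0
    a3: float = 0.0
    reference_wavenumber: float | None = None

    def phase(self, axis: SpectralAxis) -> np.ndarray:
        k_ref = self.reference_wavenumber
        if k_ref is None:
            k_ref = axis.center_wavenumber
        dkk = axis.wavenumbers - k_ref
        phi = self.a2 * dkk**2 + self.a3 * dkk**3
        if not np.all(np.isfinite(phi)):
            raise InvalidSpecError("dispersion phase is not finite over the axis")
        return phi

    def perturbed(self, delta_a2: float, delta_a3: float) -> "DispersionModel":
        return replace(self, a2=self.a2 + delta_a2, a3=self.a3 + delta_a3)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and scattering content of a synthetic sample.

    ``layer_boundaries`` is a list of (top depth um, mean reflectivity)
    tuples; each layer extends down to the next boundary (the last one to
    ``depth_extent``).  ``scatterer_density`` is the expected number of
    sub-resolution scatterers per resolution cell; several per cell gives
    fully developed speckle.  ``discrete_reflectors`` are deterministic
    point targets (depth um, lateral um, amplitude) emulating mirrors and
    TiO2 microspheres.
    """

    depth_extent: float = 2000.0
    lateral_extent: float = 2048.0
    layer_boundaries: Sequence[tuple[float, float]] = ()
    scatterer_density: float = 0.0
    discrete_reflectors: Sequence[tuple[float, float, float]] = ()
    axial_cell_um: float = 5.0
    lateral_cell_um: float = 13.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_extent <= 0 or self.lateral_extent <= 0:
            raise InvalidSpecError("phantom extents must be positive")
        if self.scatterer_density < 0:
            raise InvalidSpecError("scatterer_density must be >= 0")
        for z, _x, a in self.discrete_reflectors:
            if a < 0:
                raise InvalidSpecError("reflector amplitudes must be >= 0")
            if not (0 <= z <= self.depth_extent):
                raise InvalidSpecError("reflector depth outside phantom")
        for z, r in self.layer_boundaries:
            if not (0 <= z <= self.depth_extent):
                raise InvalidSpecError("layer boundary outside phantom")
            if r < 0:
                raise InvalidSpecError("layer reflectivity must be >= 0")


@dataclass
class ScattererField:
    """A set of point scatterers: depths/laterals in um, complex amplitudes."""

    depths: np.ndarray
    laterals: np.ndarray
    amplitudes: np.ndarray  # complex
    spec: PhantomSpec | None = None
    layer_index: np.ndarray | None = None  # -1 for discrete reflectors

    def __len__(self) -> int:
        return len(self.depths)

    def column(self, lateral_um: float, beam_fwhm_um: float = 13.0,
               cutoff: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
        """Scatterers seen by a Gaussian beam centred at ``lateral_um``.

        Returns (depths, complex amplitudes) weighted by the Gaussian beam
        amplitude profile; contributions below ``cutoff`` are dropped.
        """
        if len(self) == 0:
            return np.empty(0), np.empty(0, dtype=complex)
        w = np.exp(-4.0 * np.log(2.0) * ((self.laterals - lateral_um) / beam_fwhm_um) ** 2)
        keep = w > cutoff
        return self.depths[keep], self.amplitudes[keep] * w[keep]


def _layer_spans(spec: PhantomSpec) -> list[tuple[float, float, float]]:
    """(z_top, z_bottom, reflectivity) for each layer."""
    bounds = sorted(spec.layer_boundaries, key=lambda t: t[0])
    spans = []
    for i, (z_top, refl) in enumerate(bounds):
        z_bot = bounds[i + 1][0] if i + 1 < len(bounds) else spec.depth_extent
        if z_bot > z_top:
            spans.append((z_top, z_bot, refl))
    return spans


def make_phantom(spec: PhantomSpec) -> ScattererField:
    """Draw the scatterer field of a phantom.

    Layer scatterer counts are Poisson with mean density x number of
    resolution cells in the layer; random scatterers carry circular complex
    Gaussian amplitudes scaled by the layer reflectivity (speckle
    statistics), discrete reflectors carry their stated real amplitude.
    Deterministic for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5CA77E]))
    depths, laterals, amps, layer_idx = [], [], [], []
    n_lat_cells = max(spec.lateral_extent / spec.lateral_cell_um, 1.0)
    for li, (z_top, z_bot, refl) in enumerate(_layer_spans(spec)):
        if spec.scatterer_density <= 0 or refl <= 0:
            continue
        n_ax_cells = max((z_bot - z_top) / spec.axial_cell_um, 1.0)
        n = rng.poisson(spec.scatterer_density * n_ax_cells * n_lat_cells)
        if n == 0:
            continue
        depths.append(rng.uniform(z_top, z_bot, n))
        laterals.append(rng.uniform(0.0, spec.lateral_extent, n))
        re, im = rng.standard_normal(n), rng.standard_normal(n)
        amps.append(refl * (re + 1j * im) / np.sqrt(2.0))
        layer_idx.append(np.full(n, li))
    for z, x, a in spec.discrete_reflectors:
        depths.append(np.array([z]))
        laterals.append(np.array([x]))
        amps.append(np.array([a + 0.0j]))
        layer_idx.append(np.array([-1]))
    if depths:
        return ScattererField(
            np.concatenate(depths), np.concatenate(laterals),
            np.concatenate(amps), spec, np.concatenate(layer_idx))
    return ScattererField(np.empty(0), np.empty(0), np.empty(0, dtype=complex),
                          spec, np.empty(0, dtype=int))


@dataclass
class FringeRecord:
    """One A-scan's raw real-valued interference spectrum.

    ``samples`` includes the non-interferometric background term stored
    separately in ``background`` so the reconstruction chain can subtract it.
    """

    samples: np.ndarray
    background: np.ndarray
    axis: SpectralAxis
    dispersion: DispersionModel = field(default_factory=DispersionModel)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.samples.shape != (self.axis.n_samples,):
            raise InvalidSpecError("fringe length must equal axis.n_samples")
        if self.background.shape != self.samples.shape:
            raise InvalidSpecError("background length must match samples")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidSpecError("fringe samples must be finite")


_BACKGROUND_LEVEL = 10.0  # reference-arm spectral amplitude (arb. detector units)


def simulate_fringe(depths_um: np.ndarray, amplitudes: np.ndarray,
                    axis: SpectralAxis,
                    dispersion: DispersionModel | None = None,
                    noise_std: float = 0.0,
                    seed: int = 0) -> FringeRecord:
    """Simulate the raw interference fringe of one beam column.

    samples = background + sum_i |a_i| G(k) cos(2*pi*2*z_i*k + phi_disp(k)
    + arg a_i) + N(0, noise_std), with G the Gaussian source amplitude
    envelope.  Raises :class:`OutOfRangeError` for reflectors beyond the
    unambiguous depth range of the axis.
    """
    if noise_std < 0:
        raise InvalidSpecError("noise_std must be >= 0")
    dispersion = dispersion or DispersionModel()
    depths_um = np.asarray(depths_um, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=complex)
    if depths_um.size and depths_um.max() >= axis.max_depth_um:
        raise OutOfRangeError(
            f"reflector at {depths_um.max():.1f} um beyond unambiguous "
            f"range {axis.max_depth_um:.1f} um")
    if np.any(depths_um < 0):
        raise OutOfRangeError("negative reflector depth")
    k = axis.wavenumbers
    envelope = axis.source_envelope()
    background = _BACKGROUND_LEVEL * envelope
    samples = background.copy()
    if depths_um.size:
        phi_disp = dispersion.phase(axis)
        # phase = 2*pi * (2 z) * k, z in cm
        x_cm = 2.0 * depths_um * 1.0e-4
        carrier = 2.0 * np.pi * np.outer(x_cm, k) + phi_disp[None, :]
        contrib = np.abs(amplitudes)[:, None] * np.cos(
            carrier + np.angle(amplitudes)[:, None])
        samples = samples + envelope * contrib.sum(axis=0)
    if noise_std > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF21C6E]))
        samples = samples + rng.normal(0.0, noise_std, axis.n_samples)
    return FringeRecord(samples, background, axis, dispersion)


def simulate_bscan_frame(field_: ScattererField, axis: SpectralAxis,
                         dispersion: DispersionModel | None = None,
                         noise_std: float = 0.05,
                         n_ascans: int = 1024,
                         beam_fwhm_um: float = 13.0,
                         seed: int = 0) -> list[FringeRecord]:
    """Simulate one frame: ``n_ascans`` fringes across the lateral extent."""
    spec = field_.spec
    extent = spec.lateral_extent if spec is not None else float(n_ascans)
    positions = (np.arange(n_ascans) + 0.5) * extent / n_ascans
    seeds = np.random.SeedSequence([seed, 0xB5CA17]).generate_state(n_ascans) >> 1
    frame = []
    for i, x in enumerate(positions):
        d, a = field_.column(x, beam_fwhm_um)
        frame.append(simulate_fringe(d, a, axis, dispersion, noise_std,
                                     seed=int(seeds[i])))
    return frame


def _shift_field(field_: ScattererField, resample_fraction: float,
                 rng: np.random.Generator) -> ScattererField:
    """Decorrelate a field by redrawing a fraction of its scatterers.

    Models out-of-plane motion: scatterers leaving the (finite-thickness)
    beam are replaced by fresh ones from the same layer, so layer geometry
    is preserved while speckle decorrelates.
    """
    spec = field_.spec
    if spec is None or len(field_) == 0 or resample_fraction <= 0:
        return ScattererField(field_.depths.copy(), field_.laterals.copy(),
                              field_.amplitudes.copy(), spec,
                              None if field_.layer_index is None
                              else field_.layer_index.copy())
    spans = _layer_spans(spec)
    depths = field_.depths.copy()
    laterals = field_.laterals.copy()
    amps = field_.amplitudes.copy()
    layer_idx = field_.layer_index
    redraw = rng.random(len(field_)) < resample_fraction
    if layer_idx is not None:
        redraw &= layer_idx >= 0  # discrete reflectors persist
    idx = np.nonzero(redraw)[0]
    for i in idx:
        li = int(layer_idx[i]) if layer_idx is not None else 0
        z_top, z_bot, refl = spans[li]
        depths[i] = rng.uniform(z_top, z_bot)
        laterals[i] = rng.uniform(0.0, spec.lateral_extent)
        amps[i] = refl * (rng.standard_normal() + 1j * rng.standard_normal()) / np.sqrt(2.0)
    return ScattererField(depths, laterals, amps, spec, layer_idx)


# fraction of speckle scatterers redrawn per micrometre of out-of-plane offset
DECORRELATION_PER_UM = 0.06


def simulate_bscan_stack(spec: PhantomSpec, n_frames: int,
                         frame_interval_um: float,
                         axis: SpectralAxis,
                         dispersion: DispersionModel | None = None,
                         noise_std: float = 0.05,
                         n_ascans: int = 1024,
                         beam_fwhm_um: float = 13.0,
                         seed: int = 0) -> list[list[FringeRecord]]:
    """Simulate ``n_frames`` adjacent B-scan frames separated out-of-plane.

    Frame 0 is the phantom itself; each subsequent frame redraws a fraction
    of the speckle scatterers proportional to the interval, so inter-frame
    speckle correlation decays with frame separation (the mechanism frame
    averaging exploits).  A zero interval yields identical scatterer fields.
    """
    if n_frames < 1:
        raise InvalidSpecError("n_frames must be >= 1")
    if frame_interval_um < 0:
        raise InvalidSpecError("frame_interval_um must be >= 0")
    field_ = make_phantom(spec)
    frac = min(DECORRELATION_PER_UM * frame_interval_um, 1.0)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, seed, 0xDECA11]))
    frame_seeds = np.random.SeedSequence([seed, 0xF8A3E5]).generate_state(n_frames) >> 1
    stack = []
    for j in range(n_frames):
        if j > 0:
            field_ = _shift_field(field_, frac, rng)
        noise_seed = int(frame_seeds[j]) if frame_interval_um > 0 or j == 0 else int(frame_seeds[0])
        stack.append(simulate_bscan_frame(field_, axis, dispersion, noise_std,
                                          n_ascans, beam_fwhm_um,
                                          seed=noise_seed))
    return stack


def save_fringes_h5(path, stack: list[list[FringeRecord]],
                    phantom: PhantomSpec | None = None) -> None:
    """Write a frame stack as /fringes (frames x n_ascans x n_samples f32)."""
    axis = stack[0][0].axis
    disp = stack[0][0].dispersion
    arr = np.stack([[f.samples for f in frame] for frame in stack]).astype(np.float32)
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("fringes", data=arr)
        h5.create_dataset("background", data=stack[0][0].background.astype(np.float32))
        ds.attrs["center_wavenumber"] = axis.center_wavenumber
        ds.attrs["span"] = axis.span
        ds.attrs["n_samples"] = axis.n_samples
        ds.attrs["source_fwhm"] = axis.source_fwhm
        ds.attrs["dispersion_a2"] = disp.a2
        ds.attrs["dispersion_a3"] = disp.a3
        if phantom is not None:
            h5.attrs["phantom"] = json.dumps({
                "depth_extent": phantom.depth_extent,
                "lateral_extent": phantom.lateral_extent,
                "layer_boundaries": [list(t) for t in phantom.layer_boundaries],
                "scatterer_density": phantom.scatterer_density,
                "discrete_reflectors": [list(t) for t in phantom.discrete_reflectors],
                "seed": phantom.seed,
            })


def load_fringes_h5(path) -> tuple[list[list[FringeRecord]], DispersionModel]:
    """Read a stack written by :func:`save_fringes_h5`."""
    with h5py.File(path, "r") as h5:
        ds = h5["fringes"]
        axis = SpectralAxis(int(ds.attrs["n_samples"]),
                            float(ds.attrs["center_wavenumber"]),
                            float(ds.attrs["span"]),
                            float(ds.attrs["source_fwhm"]))
        disp = DispersionModel(float(ds.attrs["dispersion_a2"]),
                               float(ds.attrs["dispersion_a3"]))
        background = np.asarray(h5["background"], dtype=float)
        arr = np.asarray(ds, dtype=float)
    stack = [[FringeRecord(a, background, axis, disp) for a in frame]
             for frame in arr]
    return stack, disp
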