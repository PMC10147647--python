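"""Training losses and evaluation metrics.

Generator losses combine pixelwise L1/L2 terms, a gradient (first-difference)
term, an MS-SSIM structural term (B-scan network only) and a binary
cross-entropy adversarial term; the discriminator loss is the usual BCE of
real-vs-generated labels.  Default weights: NetA (1, 0.6, 0.9, 1e-4); NetB
(0.8, 0.6, 1, 0.9, 1e-4).

All losses are written on the package's autodiff tensors so the training
loop can backpropagate through them; passing plain numpy arrays returns a
plain float.  Gradient losses average over the first-difference arrays
(L1 of adjacent-pixel differences); constant offsets therefore contribute
nothing.

Evaluation metrics: MSE, SSIM (11x11 Gaussian window, sigma 1.5, standard
stabilizers), MS-SSIM (5 scales), PSNR with peak = reference maximum, the
beta parameter (zero-mean normalized correlation of 3x3-Laplacian-filtered
images, a despeckling feature-preservation measure) and the edge
preservation factor EPF (mean local correlation of high-pass residuals over
16x16 tiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidSpecError
from .nn import Tensor, as_tensor, no_grad
from .nn import functional as F

__all__ = [
    "LossWeights",
    "MetricsReport",
    "l1_a", "l2_a", "grad_a", "bce",
    "loss_generator_a", "loss_discriminator",
    "ms_ssim_loss", "grad_b", "loss_generator_b",
    "ssim", "ms_ssim", "psnr", "beta_parameter", "edge_preservation_factor",
    "metrics",
]

BCE_EPS = 1.0e-7


@dataclass(frozen=True)
class LossWeights:
    """Loss-term weights (lambda_1..lambda_4 for NetA, .._5 for NetB)."""

    net_a: tuple[float, float, float, float] = (1.0, 0.6, 0.9, 1.0e-4)
    net_b: tuple[float, float, float, float, float] = (0.8, 0.6, 1.0, 0.9, 1.0e-4)


def _wrap(*arrays):
    """Promote inputs to Tensors; report whether any carried a graph."""
    tensors = [as_tensor(a) for a in arrays]
    live = any(isinstance(a, Tensor) for a in arrays)
    return tensors, live


def _ret(value: Tensor, live: bool):
    return value if live else value.item()


def _check_same_shape(a, b):
    if a.shape != b.shape:
        raise InvalidSpecError(f"shape mismatch: {a.shape} vs {b.shape}")


def l1_a(out, gt):
    """Mean absolute difference of two A-scans."""
    (o, g), live = _wrap(out, gt)
    _check_same_shape(o, g)
    return _ret((o - g).abs().mean(), live)


def l2_a(out, gt):
    """Mean squared difference of two A-scans."""
    (o, g), live = _wrap(out, gt)
    _check_same_shape(o, g)
    return _ret(((o - g) ** 2).mean(), live)


def _axial_diff(t: Tensor) -> Tensor:
    """First differences along the last (depth) axis."""
    sl_hi = (Ellipsis, slice(1, None))
    sl_lo = (Ellipsis, slice(None, -1))
    return t[sl_hi] - t[sl_lo]


def grad_a(out, gt):
    """Mean absolute difference of axial first differences."""
    (o, g), live = _wrap(out, gt)
    _check_same_shape(o, g)
    return _ret((_axial_diff(o) - _axial_diff(g)).abs().mean(), live)


def bce(x, y, n: int | None = None):
    """Binary cross entropy, mean over outputs; x clamped to (eps, 1-eps)."""
    (xt, yt), live = _wrap(x, y)
    xt = xt.clip(BCE_EPS, 1.0 - BCE_EPS)
    val = -(yt * xt.log() + (1.0 - yt) * (1.0 - xt).log()).mean()
    return _ret(val, live)


def loss_generator_a(out, gt, d_of_g, w: LossWeights | None = None):
    """NetA generator loss: l1*L1 + l2*L2 + l3*L_grad + l4*BCE(D(G), 1)."""
    w = (w or LossWeights()).net_a
    (o, g, d), live = _wrap(out, gt, d_of_g)
    ones = np.ones_like(np.atleast_1d(d.data))
    val = (w[0] * l1_a(o, g) + w[1] * l2_a(o, g) + w[2] * grad_a(o, g)
           + w[3] * bce(d, ones))
    return _ret(val, live)


def loss_discriminator(d_real, d_fake):
    """BCE(D(real), 1) + BCE(D(fake), 0)."""
    (r, f), live = _wrap(d_real, d_fake)
    ones = np.ones_like(np.atleast_1d(r.data))
    zeros = np.zeros_like(np.atleast_1d(f.data))
    return _ret(bce(r, ones) + bce(f, zeros), live)


def grad_b(out, gt):
    """Sum of mean-absolute first-difference mismatches along both axes."""
    (o, g), live = _wrap(out, gt)
    _check_same_shape(o, g)
    lat_o = o[(Ellipsis, slice(1, None), slice(None))] - o[(Ellipsis, slice(None, -1), slice(None))]
    lat_g = g[(Ellipsis, slice(1, None), slice(None))] - g[(Ellipsis, slice(None, -1), slice(None))]
    val = (_axial_diff(o) - _axial_diff(g)).abs().mean() + (lat_o - lat_g).abs().mean()
    return _ret(val, live)


# -- SSIM / MS-SSIM -------------------------------------------------------

MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def _gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    x = np.arange(size) - size // 2
    g = np.exp(-0.5 * (x / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def _ssim_maps(x: Tensor, y: Tensor, data_range: float,
               win_size: int = 11, sigma: float = 1.5,
               k1: float = 0.01, k2: float = 0.03):
    """Valid-region SSIM and contrast-structure maps for NCHW tensors."""
    w = Tensor(_gaussian_window(win_size, sigma)[None, None].astype(x.data.dtype))
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_x = F.conv2d(x, w)
    mu_y = F.conv2d(y, w)
    sxx = F.conv2d(x * x, w) - mu_x * mu_x
    syy = F.conv2d(y * y, w) - mu_y * mu_y
    sxy = F.conv2d(x * y, w) - mu_x * mu_y
    lum = (2.0 * mu_x * mu_y + c1) / (mu_x * mu_x + mu_y * mu_y + c1)
    cs = (2.0 * sxy + c2) / (sxx + syy + c2)
    return lum * cs, cs


def _to_nchw(a: Tensor) -> Tensor:
    if a.ndim == 2:
        return a.reshape(1, 1, *a.shape)
    if a.ndim == 3:
        return a.reshape(a.shape[0], 1, *a.shape[1:])
    return a


def ssim(x, y, data_range: float | None = None):
    """Mean structural similarity (11x11 Gaussian window, sigma 1.5)."""
    (xt, yt), live = _wrap(x, y)
    _check_same_shape(xt, yt)
    if data_range is None:
        data_range = float(np.ptp(yt.data)) or 1.0
    s, _ = _ssim_maps(_to_nchw(xt), _to_nchw(yt), data_range)
    return _ret(s.mean(), live)


def ms_ssim(x, y, data_range: float | None = None, n_scales: int = 5,
            weights=MS_SSIM_WEIGHTS):
    """Multi-scale SSIM over ``n_scales`` dyadic scales.

    Contrast-structure means of the finer scales and the full SSIM of the
    coarsest scale are combined as a weighted geometric mean (negative
    means are clipped at zero, the usual convention).
    """
    (xt, yt), live = _wrap(x, y)
    _check_same_shape(xt, yt)
    if data_range is None:
        data_range = float(np.ptp(yt.data)) or 1.0
    weights = np.asarray(weights[:n_scales], dtype=float)
    weights = weights / weights.sum()
    xt, yt = _to_nchw(xt), _to_nchw(yt)
    if min(xt.shape[-2:]) < 11 * 2 ** (n_scales - 1):
        raise InvalidSpecError(
            f"image too small for {n_scales}-scale MS-SSIM")
    total = None
    for level in range(n_scales):
        s, cs = _ssim_maps(xt, yt, data_range)
        term = (s if level == n_scales - 1 else cs).mean().relu() ** weights[level]
        total = term if total is None else total * term
        if level < n_scales - 1:
            xt, yt = F.avg_pool2d(xt, 2), F.avg_pool2d(yt, 2)
    return _ret(total, live)


def max_feasible_scales(height: int, width: int, limit: int = 5) -> int:
    """Largest dyadic MS-SSIM scale count the image size supports."""
    n = int(np.floor(np.log2(min(height, width) / 11.0))) + 1
    return max(1, min(limit, n))


def ms_ssim_loss(out, gt, data_range: float = 2.0, n_scales: int = 5):
    """(1 - MS-SSIM)/2; in [0, 1] for images normalized to [-1, 1]."""
    (o, g), live = _wrap(out, gt)
    return _ret((1.0 - ms_ssim(o, g, data_range, n_scales)) / 2.0, live)


def loss_generator_b(out, gt, d_of_g, w: LossWeights | None = None,
                     data_range: float = 2.0, ms_ssim_scales: int = 5):
    """NetB generator loss: L1 + L2 + MS-SSIM + gradient + adversarial."""
    w = (w or LossWeights()).net_b
    (o, g, d), live = _wrap(out, gt, d_of_g)
    ones = np.ones_like(np.atleast_1d(d.data))
    val = (w[0] * l1_a(o, g) + w[1] * l2_a(o, g)
           + w[2] * ms_ssim_loss(o, g, data_range, ms_ssim_scales)
           + w[3] * grad_b(o, g) + w[4] * bce(d, ones))
    return _ret(val, live)


# -- evaluation metrics ---------------------------------------------------

_LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def psnr(out: np.ndarray, ref: np.ndarray) -> float:
    """10*log10(peak^2 / MSE) with peak = reference maximum."""
    out = np.asarray(out, dtype=float)
    ref = np.asarray(ref, dtype=float)
    mse = float(np.mean((out - ref) ** 2))
    if mse == 0.0:
        return float("inf")
    peak = float(ref.max())
    return 10.0 * np.log10(peak**2 / mse)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0.0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float((a * b).sum() / denom)


def beta_parameter(out: np.ndarray, ref: np.ndarray) -> float:
    """Normalized correlation of 3x3-Laplacian-filtered images."""
    lo = ndimage.convolve(np.asarray(out, dtype=float), _LAPLACIAN, mode="nearest")
    lr = ndimage.convolve(np.asarray(ref, dtype=float), _LAPLACIAN, mode="nearest")
    return _pearson(lo, lr)


def edge_preservation_factor(out: np.ndarray, ref: np.ndarray,
                             tile: int = 16) -> float:
    """Mean local correlation of high-pass residuals over square tiles.

    The residual is the image minus its 3x3 mean-filtered version; tiles
    with negligible reference variance are skipped.
    """
    out = np.asarray(out, dtype=float)
    ref = np.asarray(ref, dtype=float)
    ro = out - ndimage.uniform_filter(out, 3, mode="nearest")
    rr = ref - ndimage.uniform_filter(ref, 3, mode="nearest")
    h, w = ref.shape
    corrs = []
    thresh = 1e-12 * max(float(np.ptp(ref)) ** 2, 1e-30)
    for i in range(0, h - tile + 1, tile):
        for j in range(0, w - tile + 1, tile):
            to = ro[i: i + tile, j: j + tile]
            tr = rr[i: i + tile, j: j + tile]
            if np.var(tr) <= thresh or np.var(to) <= thresh:
                continue
            corrs.append(_pearson(to, tr))
    return float(np.mean(corrs)) if corrs else 1.0


@dataclass
class MetricsReport:
    """Image-pair quality metrics; resolutions are filled in by callers
    that have bead profiles to measure."""

    mse: float
    ssim: float
    ms_ssim: float
    psnr_db: float
    beta: float
    epf: float
    mode: str = "vs_ground_truth"
    axial_fwhm_um: float | None = None
    lateral_fwhm_um: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def metrics(out, ref, mode: str = "vs_ground_truth",
            data_range: float | None = None) -> MetricsReport:
    """Full metric suite for an image pair.

    ``mode`` records whether ``ref`` is a ground truth or the unenhanced
    input (the latter is how despeckling studies report PSNR/beta/EPF).
    """
    out_a = out.values if hasattr(out, "values") else np.asarray(out, dtype=float)
    ref_a = ref.values if hasattr(ref, "values") else np.asarray(ref, dtype=float)
    if out_a.shape != ref_a.shape:
        raise InvalidSpecError("metric inputs must share a shape")
    if mode not in ("vs_ground_truth", "vs_input"):
        raise InvalidSpecError("mode must be vs_ground_truth or vs_input")
    if data_range is None:
        data_range = float(np.ptp(ref_a)) or 1.0
    with no_grad():
        s = ssim(out_a, ref_a, data_range)
        try:
            ms = ms_ssim(out_a, ref_a, data_range)
        except InvalidSpecError:
            ms = ssim(out_a, ref_a, data_range)
    return MetricsReport(
        mse=float(np.mean((out_a - ref_a) ** 2)),
        ssim=s,
        ms_ssim=ms,
        psnr_db=psnr(out_a, ref_a),
        beta=beta_parameter(out_a, ref_a),
        epf=edge_preservation_factor(out_a, ref_a),
        mode=mode,
    )
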