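"""Dataset management, GAN training and the sequential inference chain.

The training corpus is organised as samples x sets x frames (a "set" is one
acquisition of consecutive B-scans over a region).  Train/test splitting
operates on whole sets so no set leaks frames across the split; the default
ratio 8:2 with 12 samples x 5 sets x 1000 frames reproduces the study
arithmetic (60,000 B-scans; 48,000 train / 12,000 test).

Training alternates one generator and one discriminator Adam step per
batch.  Inference (:func:`enhance`) runs the NetA generator over all
adjacent fringe pairs of a frame (the last column pairs with its left
neighbour), assembles the enhanced A-scans into a B-scan and applies the
NetB generator once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .degrade import (DispersionEnvelope, apply_degradation_a,
                      apply_degradation_b, build_ground_truth_b,
                      calibrate_dispersion_bound, sample_degradation_a,
                      sample_degradation_b)
from .errors import InvalidSpecError
from .nets import Discriminator, GeneratorA, GeneratorB, NetworkSpec, build_network
from .objectives import (LossWeights, loss_discriminator, loss_generator_a,
                         loss_generator_b)
from .recon import (BScanImage, default_normalization_window, normalize,
                    reconstruct_ascan, reconstruct_bscan, spectrogram)
from .simulate import DispersionModel, FringeRecord

logger = logging.getLogger("fringeoct")

__all__ = [
    "DatasetManifest", "TrainConfig", "make_dataset_manifest", "augment_a",
    "prepare_pairs_a", "prepare_pairs_b", "train", "enhance",
    "derive_seeds",
]


def derive_seeds(master_seed: int, n: int, stream: str = "") -> list[int]:
    """Fan one master seed out to ``n`` independent child seeds (< 2^31).

    The derivation hashes (master, stream-label) through numpy's
    SeedSequence so the simulator, samplers, augmentation and weight
    initialisation draw from decoupled streams.
    """
    label = sum(bytearray(stream.encode())) if stream else 0
    state = np.random.SeedSequence([master_seed, label]).generate_state(n)
    return [int(s) >> 1 for s in state]


# -- dataset manifest -----------------------------------------------------

@dataclass(frozen=True)
class ManifestRecord:
    sample_id: int
    set_id: int
    frame_index: int


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    split: dict[tuple[int, int], str]  # (sample, set) -> "train" | "test"

    def subset(self, which: str) -> list[ManifestRecord]:
        return [r for r in self.records
                if self.split[(r.sample_id, r.set_id)] == which]

    def __len__(self) -> int:
        return len(self.records)


def make_dataset_manifest(n_samples: int, sets_per_sample: int,
                          frames_per_set: int, train_ratio: float = 0.8,
                          seed: int = 0) -> DatasetManifest:
    """Enumerate records and split whole sets per sample at ``train_ratio``.

    The per-sample train set count is rounded down when the ratio does not
    divide evenly (logged); set assignment within a sample is a seeded
    permutation, so the split is reproducible and leakage-free.
    """
    if not (0.0 < train_ratio < 1.0):
        raise InvalidSpecError("train_ratio must be in (0, 1)")
    if min(n_samples, sets_per_sample, frames_per_set) <= 0:
        raise InvalidSpecError("manifest counts must be positive")
    records = [ManifestRecord(s, g, f)
               for s in range(n_samples)
               for g in range(sets_per_sample)
               for f in range(frames_per_set)]
    n_train = int(train_ratio * sets_per_sample)
    if abs(train_ratio * sets_per_sample - n_train) > 1e-9:
        logger.info("train_ratio x sets_per_sample is fractional; "
                    "rounding train count down to %d", n_train)
    if sets_per_sample == 1:
        # an indivisible set lands wholly on one side, by ratio majority
        n_train = 1 if train_ratio >= 0.5 else 0
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B117]))
    split: dict[tuple[int, int], str] = {}
    for s in range(n_samples):
        order = rng.permutation(sets_per_sample)
        for rank, g in enumerate(order):
            split[(s, int(g))] = "train" if rank < n_train else "test"
    return DatasetManifest(records, split)


# -- augmentation ---------------------------------------------------------

def augment_a(frame: list[FringeRecord], seed: int
              ) -> tuple[tuple[FringeRecord, FringeRecord], bool]:
    """Draw one adjacent fringe pair from a frame, randomly order-flipped.

    Returns ((first, second), flipped); with probability 0.5 the pair order
    (and hence the input channel order) is reversed, mirroring horizontal
    flipping of the B-scan.
    """
    if len(frame) < 2:
        raise InvalidSpecError("frame must hold at least 2 fringes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA06A]))
    i = int(rng.integers(0, len(frame) - 1))
    flip = bool(rng.random() < 0.5)
    pair = (frame[i + 1], frame[i]) if flip else (frame[i], frame[i + 1])
    return pair, flip


# -- training-pair preparation -------------------------------------------

def _neta_input(spect1, spect2, ascan1, ascan2) -> np.ndarray:
    """Stack two spectrograms and two band-broadcast A-scans as 4 channels."""
    bands = spect1.shape[0]
    return np.stack([
        spect1, spect2,
        np.broadcast_to(ascan1, (bands, ascan1.shape[-1])),
        np.broadcast_to(ascan2, (bands, ascan2.shape[-1])),
    ]).astype(np.float32)


def prepare_pairs_a(frames: list[list[FringeRecord]],
                    envelope: DispersionEnvelope,
                    compensation: DispersionModel,
                    n_pairs: int, seed: int) -> list[dict]:
    """Build NetA training records: degraded (spectrograms + A-scans) vs
    the optimal A-scan of the pair's first fringe."""
    pairs = []
    seeds = derive_seeds(seed, 2 * n_pairs, "prepare_a")
    for j in range(n_pairs):
        frame = frames[j % len(frames)]
        (f1, f2), _ = augment_a(frame, seeds[2 * j])
        spec = sample_degradation_a(envelope, seeds[2 * j + 1])
        _, a1, s1 = apply_degradation_a(f1, spec, compensation)
        _, a2, s2 = apply_degradation_a(f2, spec, compensation)
        gt = reconstruct_ascan(f1, compensation)
        floor, ceil = default_normalization_window(gt.values)
        pairs.append({
            "input": _neta_input(normalize(s1.values, floor, ceil),
                                 normalize(s2.values, floor, ceil),
                                 normalize(a1.values, floor, ceil),
                                 normalize(a2.values, floor, ceil)),
            "gt": normalize(gt.values, floor, ceil).astype(np.float32),
            "window": (floor, ceil),
            "spec": spec,
        })
    return pairs


def prepare_pairs_b(stacks: list[list[list[FringeRecord]]],
                    compensation: DispersionModel,
                    seed: int,
                    patch: int | None = None) -> list[dict]:
    """Build NetB training records from 7-frame stacks.

    The input is the degraded centre frame; the ground truth is the
    Gaussian-weighted average of the 7 optimally reconstructed frames,
    normalized with the same window as the input.  ``patch`` optionally
    crops a square region (keeps desk-scale training affordable).
    """
    records = []
    seeds = derive_seeds(seed, len(stacks), "prepare_b")
    for stack, s in zip(stacks, seeds):
        if len(stack) != 7:
            raise InvalidSpecError("NetB stacks must hold 7 frames")
        spec = sample_degradation_b(s)
        degraded, window = apply_degradation_b(stack[3], spec, compensation)
        optimal = [reconstruct_bscan(fr, compensation) for fr in stack]
        gt = build_ground_truth_b(optimal)
        gt_norm = normalize(gt.values, *window)
        x, y = degraded.values, gt_norm
        if patch is not None:
            h, w = x.shape
            rng = np.random.default_rng(np.random.SeedSequence([s, 0xB9A7C4]))
            i = int(rng.integers(0, max(h - patch, 0) + 1))
            j = int(rng.integers(0, max(w - patch, 0) + 1))
            x = x[i: i + patch, j: j + patch]
            y = y[i: i + patch, j: j + patch]
        records.append({"input": x.astype(np.float32),
                        "gt": y.astype(np.float32),
                        "window": window, "spec": spec})
    return records


# -- training -------------------------------------------------------------

@dataclass
class TrainConfig:
    net: str = "A"  # "A" | "B"
    epochs: int = 5
    batch_size: int = 8
    learning_rate: float = 1.0e-4
    seed: int = 0
    base_channels: int = 8
    loss_weights: LossWeights = field(default_factory=LossWeights)
    ms_ssim_scales: int = 5
    checkpoint_path: str | None = None

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate < 0:
            raise InvalidSpecError("epochs/batch must be positive, lr >= 0")
        if self.net not in ("A", "B"):
            raise InvalidSpecError("net must be 'A' or 'B'")


@dataclass
class TrainResult:
    generator: nn.Module
    discriminator: nn.Module
    history: dict[str, list[float]]


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i: i + batch_size]


def train(pairs: list[dict], config: TrainConfig) -> TrainResult:
    """Alternating GAN training (one generator step, one discriminator step
    per batch).  Raises on divergence (non-finite loss); logs per-epoch
    mean generator/discriminator losses to the history."""
    net_seed, shuffle_seed = derive_seeds(config.seed, 2, "train")
    if config.net == "A":
        gen = GeneratorA(NetworkSpec("generator_a", config.base_channels, net_seed))
        disc = Discriminator(NetworkSpec("discriminator_a", config.base_channels, net_seed))
    else:
        gen = GeneratorB(NetworkSpec("generator_b", config.base_channels, net_seed))
        disc = Discriminator(NetworkSpec("discriminator_b", config.base_channels, net_seed))
    opt_g = nn.Adam(gen.parameters(), lr=config.learning_rate)
    opt_d = nn.Adam(disc.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(shuffle_seed)
    history = {"generator": [], "discriminator": []}
    for epoch in range(config.epochs):
        g_losses, d_losses = [], []
        for idx in _batches(len(pairs), config.batch_size, rng):
            xb = np.stack([pairs[i]["input"] for i in idx])
            yb = np.stack([pairs[i]["gt"] for i in idx])
            if config.net == "B":
                xb = xb[:, None]      # (N, 1, H, W)
                yb_t = yb[:, None]
            else:
                yb_t = yb
            # generator step
            gen.train(); disc.train()
            out = gen(nn.Tensor(xb))
            d_of_g = disc(out)
            if config.net == "A":
                loss_g = loss_generator_a(out, nn.Tensor(yb_t), d_of_g,
                                          config.loss_weights)
            else:
                loss_g = loss_generator_b(out, nn.Tensor(yb_t), d_of_g,
                                          config.loss_weights,
                                          ms_ssim_scales=config.ms_ssim_scales)
            if not np.isfinite(loss_g.data):
                raise RuntimeError(
                    f"training diverged: non-finite generator loss at epoch {epoch}")
            opt_g.zero_grad(); opt_d.zero_grad()
            loss_g.backward(np.asarray(1.0, dtype=np.float32))
            opt_g.step()
            # discriminator step
            d_real = disc(nn.Tensor(yb_t))
            d_fake = disc(nn.Tensor(out.data))  # detached generator output
            loss_d = loss_discriminator(d_real, d_fake)
            if not np.isfinite(loss_d.data):
                raise RuntimeError(
                    f"training diverged: non-finite discriminator loss at epoch {epoch}")
            opt_d.zero_grad()
            loss_d.backward(np.asarray(1.0, dtype=np.float32))
            opt_d.step()
            g_losses.append(float(loss_g.data))
            d_losses.append(float(loss_d.data))
        history["generator"].append(float(np.mean(g_losses)))
        history["discriminator"].append(float(np.mean(d_losses)))
        logger.info("epoch %d: G=%.5f D=%.5f", epoch,
                    history["generator"][-1], history["discriminator"][-1])
    return TrainResult(gen, disc, history)


# -- inference ------------------------------------------------------------

def _neta_infer_columns(gen_a, frame, compensation, window,
                        batch: int = 32) -> np.ndarray:
    """Run NetA over all adjacent pairs; returns (depth, n_columns)."""
    floor, ceil = window
    spects, ascans = [], []
    for f in frame:
        spects.append(normalize(spectrogram(f).values, floor, ceil))
        ascans.append(normalize(reconstruct_ascan(f, compensation).values,
                                floor, ceil))
    n = len(frame)
    inputs = []
    for i in range(n):
        j = i + 1 if i + 1 < n else i - 1  # last column pairs leftward
        inputs.append(_neta_input(spects[i], spects[j], ascans[i], ascans[j]))
    depth = ascans[0].shape[-1]
    out = np.empty((depth, n), dtype=np.float32)
    gen_a.eval()
    with nn.no_grad():
        for i in range(0, n, batch):
            xb = np.stack(inputs[i: i + batch])
            out[:, i: i + batch] = gen_a(nn.Tensor(xb)).data.T
    return out


def enhance(frame: list[FringeRecord], generator_a, generator_b,
            compensation: DispersionModel | None = None,
            normalization: tuple[float, float] | None = None) -> BScanImage:
    """Sequential NetA -> NetB inference on one frame of optimal fringes.

    Every A-scan is enhanced by NetA from its adjacent fringe pair, the
    results are assembled into a B-scan, and NetB produces the final
    output (same shape, values in [-1, 1]).  Deterministic given the
    checkpoints (eval mode, fixed normalization statistics).
    """
    if compensation is None:
        compensation = frame[0].dispersion
    if normalization is None:
        optimal = reconstruct_bscan(frame, compensation)
        normalization = default_normalization_window(optimal.values)
    assembled = _neta_infer_columns(generator_a, frame, compensation,
                                    normalization)
    generator_b.eval()
    with nn.no_grad():
        out = generator_b(nn.Tensor(assembled[None, None])).data[0, 0]
    return BScanImage(out.astype(float), normalized=True)
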