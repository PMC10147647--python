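"""Generator and discriminator architectures for the two enhancement GANs.

NetA (axial enhancement) maps a pair of adjacent fringes — presented as two
STFT spectrograms plus the two plain A-scans broadcast along the band axis,
stacked as four 2-D channels — to one enhanced A-scan.  Its generator has
13 blocks: a convolutional head, 4 residual-in-residual dense blocks
(RRDB), a convolution, one long-skip-connection block, four further
convolutional blocks, a convolution, and a bounded (tanh) output head that
collapses the band axis.

NetB (lateral enhancement / despeckling) maps a B-scan image to a same-shape
image through 12 blocks: head, 8 RRDBs, two convolutional blocks and a tanh
output head.

Both discriminators have 11 blocks of convolutions (stride 2 on every other
block), ending in global average pooling and a sigmoid scalar.  Every block
carries 2-D batch normalization and PReLU activation.  Channel widths are
configurable (``base_channels``) without changing block counts; RRDBs use 3
internal dense layers with residual scaling 0.2, the common convention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .errors import InvalidSpecError
from .nn import functional as F

__all__ = [
    "NetworkSpec",
    "build_generator_a",
    "build_generator_b",
    "build_discriminator",
    "build_network",
    "block_census",
    "save_checkpoint",
    "load_checkpoint",
    "GeneratorA",
    "GeneratorB",
    "Discriminator",
]

_ROLES = ("generator_a", "discriminator_a", "generator_b", "discriminator_b")


@dataclass(frozen=True)
class NetworkSpec:
    """Role, depth and width of one network; seed fixes initialisation."""

    role: str
    base_channels: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise InvalidSpecError(f"unknown role {self.role!r}")
        if self.base_channels <= 0:
            raise InvalidSpecError("base_channels must be positive")

    @property
    def n_blocks(self) -> int:
        return {"generator_a": 13, "generator_b": 12,
                "discriminator_a": 11, "discriminator_b": 11}[self.role]

    @property
    def n_rrdb(self) -> int:
        return {"generator_a": 4, "generator_b": 8,
                "discriminator_a": 0, "discriminator_b": 0}[self.role]


class ConvBlock(nn.Module):
    """conv -> batch norm -> PReLU."""

    block_kind = "conv"

    def __init__(self, cin, cout, rng, stride=1, kernel=3):
        self.conv = nn.Conv2d(cin, cout, kernel, stride=stride, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.PReLU(cout)

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class RRDB(nn.Module):
    """Residual-in-residual dense block: 3 dense conv layers, scaling 0.2."""

    block_kind = "rrdb"
    scaling = 0.2

    def __init__(self, channels, rng, growth=None):
        growth = growth or channels
        self.l1 = ConvBlock(channels, growth, rng)
        self.l2 = ConvBlock(channels + growth, growth, rng)
        self.l3 = nn.Conv2d(channels + 2 * growth, channels, 3, rng=rng)

    def forward(self, x):
        f1 = self.l1(x)
        f2 = self.l2(nn.concat([x, f1], axis=1))
        f3 = self.l3(nn.concat([x, f1, f2], axis=1))
        return x + self.scaling * f3


class SkipBlock(nn.Module):
    """conv + batch norm, then addition of the long skip, then PReLU."""

    block_kind = "skip"

    def __init__(self, channels, rng):
        self.conv = nn.Conv2d(channels, channels, 3, rng=rng)
        self.bn = nn.BatchNorm2d(channels)
        self.act = nn.PReLU(channels)

    def forward(self, x, skip):
        return self.act(self.bn(self.conv(x)) + skip)


class OutputBlock(nn.Module):
    """conv to one channel and tanh bound to [-1, 1]."""

    block_kind = "output"

    def __init__(self, channels, rng):
        self.conv = nn.Conv2d(channels, 1, 3, rng=rng)

    def forward(self, x):
        return self.conv(x).tanh()


class GeneratorA(nn.Module):
    """13-block axial-enhancement generator.

    Input (N, 4, bands, depth): channels are [spectrogram 1, spectrogram 2,
    A-scan 1 broadcast over bands, A-scan 2 broadcast over bands]; output
    (N, depth) is the enhanced A-scan of the first fringe of the pair.
    """

    def __init__(self, spec: NetworkSpec):
        if spec.role != "generator_a":
            raise InvalidSpecError("spec.role must be generator_a")
        self.spec = spec
        c = spec.base_channels
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x6E7A]))
        self.head = ConvBlock(4, c, rng)                        # block 1
        self.rrdbs = [RRDB(c, rng) for _ in range(4)]           # blocks 2-5
        self.mid = ConvBlock(c, c, rng)                         # block 6
        self.skip = SkipBlock(c, rng)                           # block 7
        self.tail = [ConvBlock(c, c, rng) for _ in range(4)]    # blocks 8-11
        self.penult = ConvBlock(c, c, rng)                      # block 12
        self.out = OutputBlock(c, rng)                          # block 13

    def forward(self, x):
        h = self.head(x)
        y = h
        for blk in self.rrdbs:
            y = blk(y)
        y = self.mid(y)
        y = self.skip(y, h)
        for blk in self.tail:
            y = blk(y)
        y = self.out(self.penult(y))
        # collapse the band axis to a single depth profile
        return y.mean(axis=(1, 2))


class GeneratorB(nn.Module):
    """12-block lateral-enhancement generator, (N, 1, H, W) -> (N, 1, H, W)."""

    def __init__(self, spec: NetworkSpec):
        if spec.role != "generator_b":
            raise InvalidSpecError("spec.role must be generator_b")
        self.spec = spec
        c = spec.base_channels
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x6E7B]))
        self.head = ConvBlock(1, c, rng)                        # block 1
        self.rrdbs = [RRDB(c, rng) for _ in range(8)]           # blocks 2-9
        self.mid = ConvBlock(c, c, rng)                         # block 10
        self.penult = ConvBlock(c, c, rng)                      # block 11
        self.out = OutputBlock(c, rng)                          # block 12

    def forward(self, x):
        y = self.head(x)
        for blk in self.rrdbs:
            y = blk(y)
        return self.out(self.penult(self.mid(y)))


class FinalBlock(nn.Module):
    """Global average pool + 1x1 conv + sigmoid -> scalar per sample."""

    block_kind = "conv"

    def __init__(self, channels, rng):
        self.conv = nn.Conv2d(channels, 1, 1, padding=0, rng=rng)

    def forward(self, x):
        pooled = x.mean(axis=(2, 3), keepdims=True)
        return self.conv(pooled).sigmoid().reshape(-1)


class Discriminator(nn.Module):
    """11-block patch critic: stride-2 downsampling on every other block."""

    def __init__(self, spec: NetworkSpec):
        if not spec.role.startswith("discriminator"):
            raise InvalidSpecError("spec.role must be a discriminator role")
        self.spec = spec
        c = spec.base_channels
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD15C]))
        # NetA discriminator sees (N, 1, 1, depth) profiles: use 1xk kernels
        kernel = (1, 3) if spec.role == "discriminator_a" else 3
        blocks = [ConvBlock(1, c, rng, kernel=kernel)]          # block 1
        for i in range(9):                                      # blocks 2-10
            stride = (1, 2) if spec.role == "discriminator_a" else 2
            blocks.append(ConvBlock(c, c, rng,
                                    stride=stride if i % 2 == 0 else 1,
                                    kernel=kernel))
        self.blocks = blocks
        self.final = FinalBlock(c, rng)                         # block 11

    def forward(self, x):
        x = nn.as_tensor(x)
        if x.ndim == 2 and self.spec.role == "discriminator_a":
            x = x.reshape(x.shape[0], 1, 1, x.shape[1])
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        y = x
        for blk in self.blocks:
            y = blk(y)
        return self.final(y)


def build_generator_a(spec: NetworkSpec) -> GeneratorA:
    return GeneratorA(spec)


def build_generator_b(spec: NetworkSpec) -> GeneratorB:
    return GeneratorB(spec)


def build_discriminator(spec: NetworkSpec) -> Discriminator:
    return Discriminator(spec)


def build_network(spec: NetworkSpec) -> nn.Module:
    if spec.role == "generator_a":
        return GeneratorA(spec)
    if spec.role == "generator_b":
        return GeneratorB(spec)
    return Discriminator(spec)


def block_census(net: nn.Module) -> dict[str, int]:
    """Count architecture blocks (modules tagged with ``block_kind``)."""
    counts = {"blocks": 0, "rrdb": 0, "skip": 0}

    def visit(m: nn.Module):
        kind = getattr(m, "block_kind", None)
        if kind is not None:
            counts["blocks"] += 1
            if kind == "rrdb":
                counts["rrdb"] += 1
            if kind == "skip":
                counts["skip"] += 1
            if kind != "rrdb":  # RRDB internals are not top-level blocks
                for _, child in m._children():
                    visit(child)
            return
        for _, child in m._children():
            visit(child)

    visit(net)
    return counts


def save_checkpoint(path, net: nn.Module) -> None:
    """Single-file archive: weights + buffers + the NetworkSpec as JSON."""
    state = net.state_dict()
    np.savez(path, __spec__=np.frombuffer(
        json.dumps(asdict(net.spec)).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> nn.Module:
    with np.load(path) as archive:
        spec = NetworkSpec(**json.loads(bytes(archive["__spec__"]).decode()))
        net = build_network(spec)
        net.load_state_dict({k: archive[k] for k in archive.files
                             if k != "__spec__"})
    return net
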