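"""Layer modules over the autodiff core (Conv2d, BatchNorm2d, PReLU, ...)."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .core import Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "PReLU", "Sequential"]


class Module:
    """Base class: parameter/buffer discovery by attribute traversal."""

    training: bool = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- checkpoint support ----------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{n}": p.data for n, p in self.named_parameters()}
        state.update({f"buffer:{n}": b for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data = np.asarray(value, dtype=params[name].data.dtype)
            else:
                buffers[name][...] = value


def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


class Conv2d(Module):
    """2-D convolution with He-normal initialisation from a provided RNG."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: int | tuple[int, int] = 3,
                 stride: int | tuple[int, int] = 1,
                 padding: int | tuple[int, int] | str = "same",
                 bias: bool = True,
                 rng: np.random.Generator | None = None):
        kh, kw = _pair(kernel_size)
        if padding == "same":
            padding = (kh // 2, kw // 2)
        self.stride = _pair(stride)
        self.padding = _pair(padding)
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (out_channels, in_channels, kh, kw))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = (Tensor(np.zeros(out_channels, dtype=np.float32),
                            requires_grad=True) if bias else None)

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum,
                            self.eps)


class PReLU(Module):
    def __init__(self, channels: int, init: float = 0.25):
        self.slope = Tensor(np.full(channels, init, dtype=np.float32),
                            requires_grad=True)

    def forward(self, x):
        return F.prelu(x, self.slope)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
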