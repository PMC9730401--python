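"""Neural-network layers built on the autodiff engine.

Provides the 3x3 conv -> batch norm -> ReLU block the encoder and decoder are
made of, 1x1 projections for the attention gates, and the RMSprop optimizer.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable and running-statistic arrays, in module order."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]):
        it = iter(arrays)
        for p in self.parameters():
            p.data = np.asarray(next(it), dtype=p.data.dtype).reshape(p.data.shape)
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(next(it), dtype=np.float64).ravel()
                m.running_var = np.asarray(next(it), dtype=np.float64).ravel()


class Conv2d(Module):
    """Stride-1 convolution with He-normal init; padding preserves shape."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.eps = eps
        self.momentum = momentum
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = ad.mean(x, axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = ad.mean(centered * centered, axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = centered * ad.pow_(var + self.eps, -0.5)
        else:
            dt = x.data.dtype
            mu = self.running_mean.astype(dt).reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).astype(dt).reshape(1, -1, 1, 1)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma + self.beta


class ConvBlock(Module):
    """3x3 convolution -> batch normalization -> ReLU."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.conv = Conv2d(in_channels, out_channels, 3, rng)
        self.bn = BatchNorm2d(out_channels)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        return ad.relu(self.bn(self.conv(x)))


class AttentionGate(Module):
    """Additive attention gate on a skip connection.

    Skip and gating features are projected to `inter_channels` by 1x1
    convolutions, summed, passed through ReLU, projected to a single channel
    and squashed by a sigmoid. The resulting [0, 1] mask multiplies the skip
    features, suppressing responses outside the attended region.
    """

    def __init__(self, skip_channels: int, gate_channels: int,
                 inter_channels: int | None, rng: np.random.Generator):
        if inter_channels is None:
            inter_channels = max(1, skip_channels // 2)
        self.proj_skip = Conv2d(skip_channels, inter_channels, 1, rng)
        self.proj_gate = Conv2d(gate_channels, inter_channels, 1, rng)
        self.proj_mask = Conv2d(inter_channels, 1, 1, rng)
        self.last_mask: np.ndarray | None = None
        self.training = True

    def __call__(self, skip: Tensor, gate: Tensor) -> Tensor:
        g = self.proj_gate(gate)
        if g.shape[2:] != skip.shape[2:]:
            # project at the gate's native (coarse) resolution, then resample:
            # a 1x1 conv commutes exactly with bilinear interpolation, and the
            # projected map is far smaller than the raw gating features
            g = ad.resize_bilinear(g, skip.shape[2], skip.shape[3])
        if g.shape[2:] != skip.shape[2:]:
            raise RuntimeError(
                f"attention gate spatial mismatch: skip {skip.shape} vs gate {g.shape}"
            )
        mask = ad.sigmoid(self.proj_mask(ad.relu(self.proj_skip(skip) + g)))
        self.last_mask = mask.data
        return skip * mask


class RMSprop:
    """RMSprop with uncentered second-moment accumulator."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 alpha: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.sq = [np.zeros_like(p.data, dtype=np.float64) for p in params]

    def step(self):
        for p, sq in zip(self.params, self.sq):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            sq *= self.alpha
            sq += (1 - self.alpha) * g * g
            p.data = p.data - (self.lr * g / (np.sqrt(sq) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
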