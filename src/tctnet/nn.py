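"""Neural-network layers and optimisation on top of :mod:`tctnet.autodiff`.

Weight initialisation follows the transformer convention: truncated-normal
(sigma = 0.02, clipped at two sigma) for linear projections, fan-in-scaled
truncated-normal for convolution kernels, ones/zeros for normalisation
gain/bias. Every layer draws from an explicit numpy Generator so a model is
fully reproducible from its seed.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Conv3d",
    "ConvTranspose3d",
    "LayerNorm",
    "AdamW",
    "cosine_lr",
    "clip_grad_norm",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, sigma: float, dtype) -> np.ndarray:
    vals = rng.standard_normal(shape) * sigma
    return np.clip(vals, -2 * sigma, 2 * sigma).astype(dtype)


class Module:
    """Minimal parameter container with dotted-name state dicts."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True) -> list[str]:
        """Load matching entries; returns the names that were skipped."""
        own = dict(self.named_parameters())
        skipped = []
        for name, param in own.items():
            if name in state and state[name].shape == param.data.shape:
                param.data = np.asarray(state[name], dtype=param.data.dtype).copy()
            else:
                skipped.append(name)
        if strict and skipped:
            raise KeyError(f"missing or mismatched parameters: {skipped}")
        return skipped

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32, bias: bool = True):
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features), 0.02, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ad.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 rng: np.random.Generator, stride=1, padding=0, groups: int = 1,
                 dtype=np.float32, bias: bool = True):
        k = kernel_size if isinstance(kernel_size, (tuple, list)) else (kernel_size,) * 3
        fan_in = (in_channels // groups) * int(np.prod(k))
        sigma = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            trunc_normal(rng, (out_channels, in_channels // groups, *k), sigma, dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class ConvTranspose3d(Module):
    """Transposed convolution with kernel size == stride (x2 upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 stride=2, dtype=np.float32, bias: bool = True):
        k = stride if isinstance(stride, (tuple, list)) else (stride,) * 3
        fan_in = in_channels  # each output voxel sees exactly one input voxel
        sigma = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            trunc_normal(rng, (in_channels, out_channels, *k), sigma, dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose3d(x, self.weight, self.bias, self.stride)


class LayerNorm(Module):
    """Normalises over the last (channel) axis."""

    def __init__(self, dim: int, dtype=np.float32, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta, self.eps)


# ---------------------------------------------------------------------------
# optimisation


def clip_grad_norm(params, max_norm: float) -> float:
    total = math.sqrt(
        sum(float((p.grad * p.grad).sum()) for p in params if p.grad is not None)
    )
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from base_lr at epoch 0 towards 0 at the final epoch."""
    if total_epochs <= 1:
        return base_lr
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / total_epochs))


class AdamW(Module):
    """AdamW with decoupled weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-5):
        self._params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self._params]
        self._v = [np.zeros_like(p.data) for p in self._params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self._params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * (g * g)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self._params:
            p.grad = None
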