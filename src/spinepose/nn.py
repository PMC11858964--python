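"""Minimal neural-network layer and optimizer API over :mod:`spinepose.autodiff`.

Modules hold named :class:`Parameter` tensors; ``state_dict`` /
``load_state_dict`` round-trip through plain dicts of numpy arrays so
checkpoints can be stored as ``.npz``. Initialization is He-style scaled for
leaky-ReLU activations and fully determined by the ``rng`` passed to each
layer constructor.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor

__all__ = ["Parameter", "Module", "Conv2d", "Conv3d", "Linear", "Adam"]

DEFAULT_DTYPE = np.float32


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data))
        self.requires_grad = True


class Module:
    """Base class with recursive parameter discovery over attributes/lists."""

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

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=p.dtype)
            if arr.shape != p.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
             slope: float = 0.1, dtype=DEFAULT_DTYPE) -> np.ndarray:
    std = np.sqrt(2.0 / ((1.0 + slope**2) * fan_in))
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv2d(Module):
    """Stride-1 'same' 2D convolution layer with odd kernel size."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE, weight_scale: float = 1.0):
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(
            weight_scale * _he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in, dtype=dtype)
        )
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias)


class Conv3d(Module):
    """Stride-1 'same' 3D convolution layer with odd kernel size."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE, weight_scale: float = 1.0):
        fan_in = in_ch * kernel**3
        self.weight = Parameter(
            weight_scale * _he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in, dtype=dtype)
        )
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv3d(self.weight, self.bias)


class Linear(Module):
    """Dense layer ``y = x W + b``."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE):
        self.weight = Parameter(_he_init(rng, (in_features, out_features), in_features, dtype=dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
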