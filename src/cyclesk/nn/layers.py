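"""Layer modules: parameter containers with a named-parameter registry.

Initialization follows a truncated-normal convention (sd 0.02, clipped at two
standard deviations) with zero biases; every module draws from the RNG it is
given so a single seed fixes the whole network.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "Linear", "FeatureNorm",
           "trunc_normal"]


def trunc_normal(rng: np.random.Generator, shape, sd: float = 0.02) -> np.ndarray:
    w = rng.normal(0.0, sd, size=shape)
    return np.clip(w, -2 * sd, 2 * sd).astype(np.float32)


class Module:
    """Base class; children register parameters and sub-modules by attribute."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor):
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor):
                        out.append((f"{key}.{i}", item))
        return out

    def freeze(self) -> None:
        for p in self.parameters():
            p.requires_grad = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"parameter name mismatch: {sorted(missing)[:5]}")
        for k, v in state.items():
            if own[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            own[k].data = v.astype(np.float32).copy()


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad = stride, pad
        self.weight = Tensor(trunc_normal(rng, (cout, cin, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32),
                           requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad = stride, pad
        self.weight = Tensor(trunc_normal(rng, (cin, cout, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32),
                           requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride,
                                  self.pad)


class Linear(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(trunc_normal(rng, (din, dout)), requires_grad=True)
        self.bias = Tensor(np.zeros(dout, np.float32),
                           requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class FeatureNorm(Module):
    """Normalize across the feature axis with learnable gain and bias.

    Batch statistics are unusable at batch size 1 (the training regime here),
    so the channel descriptor is standardized over its own features instead.
    """

    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gain = Tensor(np.ones(dim, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * ((var + self.eps) ** -0.5)
        return xhat * self.gain + self.bias
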