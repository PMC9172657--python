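"""Adaptive feature-selection generator.

Three parallel extractors see the same input slice: a residual
encoder-decoder CNN (symmetric conv/deconv stack with shortcut connections,
no pooling), a U-Net style encoder-decoder (strided 4x4 convolutions down,
transposed convolutions up, concatenation skips), and a pointwise 1x1
convolution. Their equally-shaped feature maps U1, U2, U3 are fused by
selective-kernel channel attention:

    U   = U1 + U2 + U3
    S_c = mean_{i,j} U_c(i, j)                     (global average pool)
    Z   = ReLU(Norm(W_s S))                        (compact feature, d < C)
    (a_c, b_c, c_c) = softmax(A_c Z, B_c Z, C_c Z) (per-channel branch weights)
    V_c = a_c U1_c + b_c U2_c + c_c U3_c

and a final 1x1 convolution projects V to the single-channel denoised image.
Ablation variants (single branch, plain concatenation, no pointwise branch)
are selected through :class:`GeneratorConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["GeneratorConfig", "SKFusionParams", "SKFusionState",
           "RedCNNBranch", "UNetBranch", "Conv1x1Branch", "SKFusion",
           "SKGenerator", "global_avg_pool", "compact_feature",
           "branch_softmax", "sk_fuse"]

ABLATIONS = ("full", "redcnn_only", "unet_only", "concat_no_sk", "no_conv1x1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture knobs; defaults are the full-scale configuration."""

    channels: int = 64
    redcnn_layers: int = 7          # conv depth; mirrored by deconv depth
    redcnn_kernel: int = 3
    unet_layers: int = 7            # strided stages down (and up)
    unet_kernel: int = 4
    reduction_dim: int | None = None   # d of the compact feature; None -> max(C/2, 8)
    ablation: str = "full"
    residual_output: bool = False

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}; "
                             f"one of {ABLATIONS}")

    @property
    def d(self) -> int:
        return self.reduction_dim or max(self.channels // 2, 8)


# ---------------------------------------------------------------------------
# branches

class RedCNNBranch(nn.Module):
    """Symmetric conv/deconv stack, stride 1 throughout, shortcut connections
    from every other encoder stage added before the matched decoder ReLU."""

    def __init__(self, channels: int, depth: int, kernel: int,
                 rng: np.random.Generator):
        pad = kernel // 2
        self.depth = depth
        self.convs = [nn.Conv2d(1 if i == 0 else channels, channels, kernel,
                                pad=pad, rng=rng) for i in range(depth)]
        self.deconvs = [nn.Conv2d(channels, channels, kernel, pad=pad, rng=rng)
                        for _ in range(depth)]

    def __call__(self, x: Tensor) -> Tensor:
        feats = []
        h = x
        for conv in self.convs:
            h = conv(h).relu()
            feats.append(h)
        for i, deconv in enumerate(self.deconvs):
            h = deconv(h)
            # shortcut: conv_k -> deconv_{depth-1-k}, every other pair
            k = self.depth - 1 - i
            if k >= 0 and (self.depth - 1 - k) % 2 == 0 and k < self.depth - 1:
                h = h + feats[k]
            h = h.relu()
        return h


class UNetBranch(nn.Module):
    """Strided-convolution encoder / transposed-convolution decoder with
    concatenation skips; output restored to input resolution and width C."""

    def __init__(self, channels: int, depth: int, kernel: int,
                 rng: np.random.Generator):
        pad = (kernel - 2) // 2  # k=4, s=2, p=1 halves/doubles exactly
        self.depth = depth
        self.encoders = [nn.Conv2d(1 if i == 0 else channels, channels, kernel,
                                   stride=2, pad=pad, rng=rng)
                         for i in range(depth)]
        self.decoders = [nn.ConvTranspose2d(
            channels if i == 0 else 2 * channels, channels, kernel,
            stride=2, pad=pad, rng=rng) for i in range(depth)]
        self.fuse = nn.Conv2d(channels + 1, channels, 3, pad=1, rng=rng)

    def effective_depth(self, h: int, w: int) -> int:
        d = self.depth
        while d > 0 and (h % (2 ** d) or w % (2 ** d) or min(h, w) // 2 ** d < 1):
            d -= 1
        return d

    def __call__(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        d = self.effective_depth(h, w)
        if d == 0:
            raise ValueError(f"input {h}x{w} too small for any strided stage")
        if d < self.depth:
            warnings.warn(
                f"u-net depth reduced from {self.depth} to {d} for "
                f"{h}x{w} input", stacklevel=2)
        feats = []
        out = x
        for enc in self.encoders[:d]:
            out = enc(out).relu()
            feats.append(out)
        for i in range(d):
            dec = self.decoders[i if i == 0 else self.depth - d + i]
            out = dec(out).relu()
            skip_level = d - 2 - i  # encoder output at the new resolution
            if skip_level >= 0:
                out = nn.concat([out, feats[skip_level]], axis=1)
        out = nn.concat([out, x], axis=1)
        return self.fuse(out).relu()


class Conv1x1Branch(nn.Module):
    """Pointwise projection to C channels; no spatial mixing, no activation."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv = nn.Conv2d(1, channels, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x)


# ---------------------------------------------------------------------------
# selective-kernel fusion

@dataclass
class SKFusionState:
    """Intermediate attention quantities for one fusion pass."""

    S: np.ndarray            # (N, C) channel descriptor
    Z: np.ndarray            # (N, d) compact feature
    weights: np.ndarray      # (N, n_branches, C), rows sum to 1 per channel


class SKFusionParams(nn.Module):
    """Projection W_s (C -> d) with normalization, and per-branch d -> C heads."""

    def __init__(self, channels: int, d: int, n_branches: int,
                 rng: np.random.Generator):
        if d < 1:
            raise ValueError("reduction dim d must be >= 1")
        if d >= channels:
            warnings.warn(f"reduction dim d={d} >= C={channels}: the compact "
                          "feature is not compact", stacklevel=2)
        self.channels, self.d, self.n_branches = channels, d, n_branches
        self.w_s = nn.Linear(channels, d, rng=rng)
        self.norm = nn.FeatureNorm(d)
        self.heads = [nn.Linear(d, channels, rng=rng, bias=False)
                      for _ in range(n_branches)]


def global_avg_pool(u: Tensor) -> Tensor:
    """Channel descriptor S_c: spatial mean of each channel of U. (N,C,H,W)->(N,C)."""
    if u.data.size == 0:
        raise ValueError("empty feature map")
    return u.mean(axis=(2, 3))


def compact_feature(s: Tensor, params: SKFusionParams) -> Tensor:
    """Z = ReLU(Norm(W_s S)); length d < C."""
    return params.norm(params.w_s(s)).relu()


def branch_softmax(z: Tensor, params: SKFusionParams) -> list[Tensor]:
    """Per-channel softmax over the branch logits A_c Z, B_c Z, C_c Z."""
    logits = [head(z) for head in params.heads]           # each (N, C)
    m = logits[0].data
    for lg in logits[1:]:
        m = np.maximum(m, lg.data)
    exps = [(lg - Tensor(m)).exp() for lg in logits]
    denom = exps[0]
    for e in exps[1:]:
        denom = denom + e
    inv = denom ** -1.0
    return [e * inv for e in exps]


def sk_fuse(branches: list[Tensor], params: SKFusionParams,
            return_state: bool = False):
    """Selective-kernel fusion of equally-shaped branch maps."""
    shape = branches[0].shape
    for i, b in enumerate(branches[1:], start=2):
        if b.shape != shape:
            raise ValueError(
                f"branch {i} shape {b.shape} != branch 1 shape {shape}")
    u = branches[0]
    for b in branches[1:]:
        u = u + b
    s = global_avg_pool(u)
    z = compact_feature(s, params)
    weights = branch_softmax(z, params)
    n, c = s.shape
    v = None
    for w, b in zip(weights, branches):
        term = w.reshape(n, c, 1, 1) * b
        v = term if v is None else v + term
    if return_state:
        state = SKFusionState(
            S=s.data.copy(), Z=z.data.copy(),
            weights=np.stack([w.data for w in weights], axis=1))
        return v, state
    return v


class SKFusion(nn.Module):
    def __init__(self, channels: int, d: int, n_branches: int,
                 rng: np.random.Generator):
        self.params = SKFusionParams(channels, d, n_branches, rng)

    def __call__(self, branches: list[Tensor], return_state: bool = False):
        return sk_fuse(branches, self.params, return_state=return_state)


# ---------------------------------------------------------------------------
# generator

class SKGenerator(nn.Module):
    """Full generator: branches -> fusion (per ablation) -> 1x1 projection."""

    def __init__(self, config: GeneratorConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        c = config.channels
        abl = config.ablation
        self.redcnn = (RedCNNBranch(c, config.redcnn_layers,
                                    config.redcnn_kernel, rng)
                       if abl != "unet_only" else None)
        self.unet = (UNetBranch(c, config.unet_layers, config.unet_kernel, rng)
                     if abl != "redcnn_only" else None)
        self.conv1x1 = (Conv1x1Branch(c, rng)
                        if abl in ("full", "concat_no_sk") else None)
        n_branches = {"full": 3, "concat_no_sk": 3, "no_conv1x1": 2}.get(abl, 1)
        self.fusion = (SKFusion(c, config.d, n_branches, rng)
                       if abl in ("full", "no_conv1x1") else None)
        proj_in = 3 * c if abl == "concat_no_sk" else c
        self.project = nn.Conv2d(proj_in, 1, 1, rng=rng)

    def branch_outputs(self, x: Tensor) -> list[Tensor]:
        outs = []
        if self.redcnn is not None:
            outs.append(self.redcnn(x))
        if self.unet is not None:
            outs.append(self.unet(x))
        if self.conv1x1 is not None:
            outs.append(self.conv1x1(x))
        return outs

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N,1,H,W) input, got {x.shape}")
        branches = self.branch_outputs(x)
        abl = self.config.ablation
        if abl in ("full", "no_conv1x1"):
            v = self.fusion(branches)
        elif abl == "concat_no_sk":
            v = nn.concat(branches, axis=1)
        else:
            v = branches[0]
        out = self.project(v)
        if self.config.residual_output:
            out = out + x
        return out

    def generate(self, x: np.ndarray) -> np.ndarray:
        """Inference on a 2-D image; returns a 2-D image of the same shape."""
        t = Tensor(x[None, None].astype(np.float32))
        return self(t).data[0, 0]


def generate(x: np.ndarray, config: GeneratorConfig,
             seed: int = 0) -> np.ndarray:
    """One-shot convenience wrapper: build a generator and run it."""
    return SKGenerator(config, seed=seed).generate(x)
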