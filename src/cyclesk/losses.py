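"""Training objective: adversarial, cycle-consistency and perceptual terms.

The overall objective is

    Loss = L_GAN(G, D_Y, X, Y) + L_GAN(F, D_X, Y, X)
           + lambda * L_cyc(G, F) + L_perceptual

with L_GAN the log-likelihood adversarial value E[log D(y)] + E[log(1-D(G(x)))]
(a least-squares variant is available for stability), L_cyc the L1 distance of
both cycle reconstructions, and L_perceptual the L1 distance between fixed
convolutional features of an image and its cycle reconstruction, taken at two
stages of a VGG-16-topology extractor (after the second and after the last
max-pooling layer). The extractor is frozen; by default its weights come from
a fixed-seed random initialization so nothing has to be downloaded, and a
locally stored VGG-16 weight file can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["LossConfig", "LossBundle", "PerceptualExtractor",
           "adversarial_loss", "cycle_loss", "perceptual_loss", "total_loss"]

_EPS = 1e-8


@dataclass(frozen=True)
class LossConfig:
    lambda_cyc: float = 10.0
    adversarial_form: str = "log_bce"        # or "least_squares"
    perceptual_layers: tuple[str, ...] = ("pool2", "pool5")
    perceptual_weights: tuple[float, ...] = (1.0, 1.0)
    vgg_width_factor: float = 1.0

    def __post_init__(self):
        if self.lambda_cyc < 0:
            raise ValueError("lambda_cyc must be >= 0")
        if self.adversarial_form not in ("log_bce", "least_squares"):
            raise ValueError(f"unknown adversarial_form "
                             f"{self.adversarial_form!r}")
        if len(self.perceptual_layers) != len(self.perceptual_weights):
            raise ValueError("one weight per perceptual layer required")


@dataclass
class LossBundle:
    """Named scalar terms of one step; total follows the objective exactly."""

    l_gan_g: float
    l_gan_f: float
    l_cyc: float
    l_perc: float
    lambda_cyc: float
    total: float = field(init=False)

    def __post_init__(self):
        self.total = (self.l_gan_g + self.l_gan_f
                      + self.lambda_cyc * self.l_cyc + self.l_perc)


# VGG-16 convolutional topology: widths per conv, pools after each block
_VGG_BLOCKS = ((64, 64), (128, 128), (256, 256, 256),
               (512, 512, 512), (512, 512, 512))


class PerceptualExtractor(nn.Module):
    """Frozen VGG-16-topology feature stack over 3-channel inputs.

    ``width_factor`` scales every layer width (minimum 4 channels) so the
    extractor stays affordable at desk scale; stage ids are ``pool1`` ..
    ``pool5``. Parameters never receive gradients.
    """

    def __init__(self, width_factor: float = 1.0, seed: int = 0,
                 weights_source: str = "random_fixed_seed",
                 weights_path: str | None = None):
        rng = np.random.default_rng(seed)
        self.width_factor = width_factor
        self.weights_source = weights_source
        self.convs: list[nn.Conv2d] = []
        self.block_sizes = []
        cin = 3
        for block in _VGG_BLOCKS:
            self.block_sizes.append(len(block))
            for w in block:
                cout = max(int(round(w * width_factor)), 4)
                conv = nn.Conv2d(cin, cout, 3, pad=1, rng=rng)
                # He-scaled random features: keeps activation magnitude
                # roughly constant through the 13-conv stack, so the random-
                # feature distance is informative at every stage
                fan_in = cin * 9
                conv.weight.data = rng.normal(
                    0.0, np.sqrt(2.0 / fan_in),
                    size=conv.weight.shape).astype(np.float32)
                self.convs.append(conv)
                cin = cout
        if weights_source == "pretrained_vgg16":
            if weights_path is None:
                raise ValueError(
                    "weights_source='pretrained_vgg16' needs a local "
                    "weights_path (npz of conv weights); none was given")
            self._load_pretrained(weights_path)
        elif weights_source != "random_fixed_seed":
            raise ValueError(f"unknown weights_source {weights_source!r}")
        self.freeze()

    def _load_pretrained(self, path: str) -> None:
        data = np.load(path)
        for i, conv in enumerate(self.convs):
            conv.weight.data = np.asarray(data[f"conv{i}.weight"], np.float32)
            conv.bias.data = np.asarray(data[f"conv{i}.bias"], np.float32)

    def stage_channels(self, stage: str) -> int:
        idx = int(stage[-1])
        upto = sum(self.block_sizes[:idx])
        return self.convs[upto - 1].weight.shape[0]

    def features(self, x: Tensor, stages: tuple[str, ...]) -> dict[str, Tensor]:
        """Feature maps at the requested pool stages; input (N,1,H,W) in [0,1]."""
        for s in stages:
            if s not in {f"pool{i}" for i in range(1, 6)}:
                raise ValueError(f"unknown perceptual stage {s!r}")
        h = nn.concat([x, x, x], axis=1)     # grayscale -> 3 channels
        out: dict[str, Tensor] = {}
        ci = 0
        deepest = max(int(s[-1]) for s in stages)
        for bi, nconvs in enumerate(self.block_sizes, start=1):
            for _ in range(nconvs):
                h = self.convs[ci](h).relu()
                ci += 1
            h = nn.maxpool2d(h, 2)
            name = f"pool{bi}"
            if name in stages:
                out[name] = h
            if bi == deepest:
                break
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))


def adversarial_loss(d_real, d_fake) -> Tensor:
    """log-likelihood adversarial value: mean log D(real) + mean log(1 - D(fake)).

    The discriminator ascends this quantity; the generator descends its own
    fake term. Scores must already be probabilities in [0, 1].
    """
    d_real, d_fake = _as_tensor(d_real), _as_tensor(d_fake)
    for name, t in (("d_real", d_real), ("d_fake", d_fake)):
        if t.data.min() < -1e-6 or t.data.max() > 1.0 + 1e-6:
            raise ValueError(f"{name} scores must lie in [0, 1]")
    return (d_real.clamp(_EPS, 1.0).log().mean()
            + (1.0 - d_fake).clamp(_EPS, 1.0).log().mean())


def cycle_loss(x, x_rec, y, y_rec) -> Tensor:
    """Mean absolute error of both cycle reconstructions (per-pixel mean)."""
    x, x_rec, y, y_rec = map(_as_tensor, (x, x_rec, y, y_rec))
    if x.shape != x_rec.shape or y.shape != y_rec.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_rec.shape}, "
                         f"{y.shape} vs {y_rec.shape}")
    return (x - x_rec).abs().mean() + (y - y_rec).abs().mean()


def perceptual_loss(x, x_rec, y, y_rec, phi: PerceptualExtractor,
                    cfg: LossConfig) -> Tensor:
    """Weighted L1 distance between fixed features of images and their
    cycle reconstructions, summed over the configured stages."""
    x, x_rec, y, y_rec = map(_as_tensor, (x, x_rec, y, y_rec))
    stages = cfg.perceptual_layers
    fx = phi.features(x.detach(), stages)
    fy = phi.features(y.detach(), stages)
    fxr = phi.features(x_rec, stages)
    fyr = phi.features(y_rec, stages)
    out = None
    for stage, w in zip(stages, cfg.perceptual_weights):
        term = ((fx[stage].detach() - fxr[stage]).abs().mean()
                + (fy[stage].detach() - fyr[stage]).abs().mean()) * float(w)
        out = term if out is None else out + term
    return out


def total_loss(l_gan_g: float, l_gan_f: float, l_cyc: float, l_perc: float,
               cfg: LossConfig) -> LossBundle:
    """Assemble the named bundle; total is the exact weighted combination."""
    return LossBundle(l_gan_g=float(l_gan_g), l_gan_f=float(l_gan_f),
                      l_cyc=float(l_cyc), l_perc=float(l_perc),
                      lambda_cyc=cfg.lambda_cyc)
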