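"""PatchGAN discriminator.

A ladder of stride-2 4x4 convolutions with LeakyReLU(0.2) maps the input to a
4x4 single-channel grid; each sigmoid entry x_ij is the probability that the
local region it sees belongs to the normal-dose domain, and the score of the
whole image is the mean of the 16 entries. The number of stride-2 stages is
chosen from the nominal input size (256 -> 6 stages, 64 -> 4 stages) so the
output grid stays 4x4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["PatchScoreMap", "PatchDiscriminator", "n_stages_for"]


@dataclass
class PatchScoreMap:
    scores: np.ndarray       # (4, 4), entries in [0, 1]

    @property
    def mean_score(self) -> float:
        return float(self.scores.mean())


def n_stages_for(input_size: int) -> int:
    """Stride-2 stages needed to map ``input_size`` down to a 4x4 grid."""
    if input_size < 8 or input_size % 4:
        raise ValueError(f"input size {input_size} cannot reach a 4x4 grid; "
                         "need a multiple of 4 that is at least 8")
    n = int(round(np.log2(input_size / 4)))
    if 4 * 2 ** n != input_size:
        raise ValueError(f"input size {input_size} is not 4 * 2^n")
    return n


class PatchDiscriminator(nn.Module):
    def __init__(self, input_size: int = 256, base_channels: int = 64,
                 max_channels: int = 512, seed: int = 0,
                 n_stages: int | None = None):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.n_stages = n_stages if n_stages is not None else n_stages_for(input_size)
        chans = [1]
        for i in range(self.n_stages - 1):
            chans.append(min(base_channels * 2 ** i, max_channels))
        chans.append(1)
        self.convs = [nn.Conv2d(chans[i], chans[i + 1], 4, stride=2, pad=1,
                                rng=rng) for i in range(self.n_stages)]

    def __call__(self, x: Tensor) -> Tensor:
        """Raw sigmoid score map as a tensor, (N, 1, 4, 4)."""
        n, c, h, w = x.shape
        need = 4 * 2 ** self.n_stages
        if h < need or w < need:
            raise ValueError(f"input {h}x{w} too small; the {self.n_stages}-"
                             f"stage discriminator needs at least {need}x{need}")
        out = x
        for conv in self.convs[:-1]:
            out = conv(out).leaky_relu(0.2)
        return self.convs[-1](out).sigmoid()

    def score(self, img: np.ndarray) -> PatchScoreMap:
        """Score a single 2-D image; returns the 4x4 probability grid."""
        t = Tensor(np.asarray(img, np.float32)[None, None])
        return PatchScoreMap(scores=self(t).data[0, 0])
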