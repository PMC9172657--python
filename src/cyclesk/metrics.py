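"""Image-quality metrics (RMSE, PSNR, SSIM) and CT display windowing.

RMSE is the root of the per-image mean squared pixel difference; PSNR is
10*log10(MAX^2 / MSE) with MAX defaulting to 1.0 on the normalized scale;
SSIM is

    SSIM(x, y) = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
                 / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

with c1 = (k1 L)^2, c2 = (k2 L)^2, defaults k1 = 0.01 and k2 = 0.02, averaged
over 11x11 Gaussian-weighted (sigma 1.5) local windows; the plain global-
statistics form is available via ``window=None``. Display windowing rescales
a [lo, hi] intensity band to [0, 1] for rendering only — it must never feed
back into metrics or losses.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["WindowSpec", "MetricReport", "rmse", "psnr", "ssim",
           "apply_window", "evaluate"]


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")


def rmse(i: np.ndarray, k: np.ndarray) -> float:
    i = np.asarray(i, np.float64)
    k = np.asarray(k, np.float64)
    _check_shapes(i, k)
    return float(np.sqrt(np.mean((i - k) ** 2)))


def psnr(i: np.ndarray, k: np.ndarray, max_i: float = 1.0) -> float:
    if max_i <= 0:
        raise ValueError("max_i must be > 0")
    i = np.asarray(i, np.float64)
    k = np.asarray(k, np.float64)
    _check_shapes(i, k)
    mse = np.mean((i - k) ** 2)
    if mse == 0.0:
        warnings.warn("identical images: PSNR is infinite", stacklevel=2)
        return float("inf")
    return float(10.0 * np.log10(max_i ** 2 / mse))


def ssim(x: np.ndarray, y: np.ndarray, k1: float = 0.01, k2: float = 0.02,
         data_range: float = 1.0, window: int | None = 11,
         sigma: float = 1.5) -> float:
    """Structural similarity with Gaussian local statistics.

    ``window=None`` uses global image statistics (the bare two-factor
    formula). Local mode mirrors the standard convention: Gaussian weights
    truncated at 3.5 sigma, border crop of half a window.
    """
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    _check_shapes(x, y)
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    if window is not None and window > min(x.shape):
        warnings.warn("window larger than image: falling back to global "
                      "statistics", stacklevel=2)
        window = None

    if window is None:
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cxy = np.mean((x - mx) * (y - my))
        return float((2 * mx * my + c1) * (2 * cxy + c2)
                     / ((mx * mx + my * my + c1) * (vx + vy + c2)))

    truncate = 3.5
    # radius int(truncate*sigma + 0.5) must give (window-1)/2
    sigma_eff = sigma
    r = (window - 1) // 2
    if int(truncate * sigma_eff + 0.5) != r:
        truncate = r / sigma_eff

    def filt(a):
        return gaussian_filter(a, sigma_eff, truncate=truncate)

    # sample-covariance normalization over the window, as in the common
    # reference implementation
    npix = window ** 2
    cov_norm = npix / (npix - 1)
    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)
         / ((ux * ux + uy * uy + c1) * (vx + vy + c2)))
    pad = r
    return float(s[pad:-pad or None, pad:-pad or None].mean())


@dataclass(frozen=True)
class WindowSpec:
    """Display window on the normalized [0, 1] scale (e.g. 0.2-0.28 tissue,
    0-0.33 lung)."""

    lo: float
    hi: float

    def __post_init__(self):
        if self.lo >= self.hi:
            raise ValueError(f"window lo {self.lo} must be < hi {self.hi}")


def apply_window(img: np.ndarray, w: WindowSpec) -> np.ndarray:
    """Linear rescale of [lo, hi] to [0, 1] with clipping; display only."""
    img = np.asarray(img, np.float64)
    return np.clip((img - w.lo) / (w.hi - w.lo), 0.0, 1.0)


@dataclass
class MetricReport:
    per_image_rmse: list[float]
    per_image_psnr: list[float]
    per_image_ssim: list[float]

    @property
    def n_images(self) -> int:
        return len(self.per_image_rmse)

    @property
    def rmse(self) -> float:
        return float(np.mean(self.per_image_rmse))

    @property
    def psnr(self) -> float:
        return float(np.mean(self.per_image_psnr))

    @property
    def ssim(self) -> float:
        return float(np.mean(self.per_image_ssim))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["image_id", "rmse", "psnr", "ssim"])
            for i in range(self.n_images):
                wr.writerow([i, f"{self.per_image_rmse[i]:.6g}",
                             f"{self.per_image_psnr[i]:.6g}",
                             f"{self.per_image_ssim[i]:.6g}"])
            wr.writerow(["mean", f"{self.rmse:.6g}", f"{self.psnr:.6g}",
                         f"{self.ssim:.6g}"])


def evaluate(pred: list[np.ndarray], truth: list[np.ndarray],
             max_i: float = 1.0, ssim_window: int | None = 11) -> MetricReport:
    """Per-image and mean RMSE / PSNR / SSIM over aligned lists."""
    if len(pred) != len(truth):
        raise ValueError(f"{len(pred)} predictions vs {len(truth)} references")
    rep = MetricReport([], [], [])
    for p, t in zip(pred, truth):
        rep.per_image_rmse.append(rmse(p, t))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep.per_image_psnr.append(psnr(p, t, max_i=max_i))
        rep.per_image_ssim.append(ssim(p, t, data_range=max_i,
                                       window=ssim_window))
    return rep
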