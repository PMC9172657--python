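"""Synthetic CT phantoms and low-dose degradation.

Clean "normal-dose" slices are ellipse composites (a body outline, random
soft-tissue ellipses, optional low-intensity lung cavities) on a normalized
[0, 1] attenuation scale. Low-dose slices are produced through a physical
pipeline: parallel-beam forward projection of the attenuation map, Poisson
photon statistics at an incident count ``photons_i0`` plus additive Gaussian
electronic noise in the sinogram, log conversion, and filtered back-projection.
Lower incident counts yield the streaky, spatially correlated noise that low
tube current causes in real scans. A fast image-domain Gaussian mode is kept
for cheap tests.

Patch extraction and unpaired dataset assembly follow the training protocol:
fixed-size patches taken every ``stride`` pixels, domains X (low-dose) and Y
(normal-dose) built from disjoint phantom cohorts and shuffled independently;
clean counterparts are retained only in a held-out evaluation split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import iradon, radon

__all__ = ["PhantomSpec", "DoseModel", "PatchDataset", "EvaluationSplit",
           "make_phantom", "simulate_low_dose", "extract_patches",
           "build_unpaired_dataset"]


class ConfigurationError(ValueError):
    """Invalid phantom / dose configuration."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic slice.

    ``intensity_range`` bounds the soft-tissue attenuation values so the
    0.2-0.28 display window of reconstructed slices shows tissue contrast;
    lung cavities sit near 0.03 for the 0-0.33 window.
    """

    image_size: int = 512
    n_ellipses: int = 8
    intensity_range: tuple[float, float] = (0.20, 0.30)
    include_lung_regions: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 8:
            raise ConfigurationError(f"image_size {self.image_size} too small")
        if self.n_ellipses < 0:
            raise ConfigurationError("n_ellipses must be >= 0")
        lo, hi = self.intensity_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigurationError(
                f"intensity_range {self.intensity_range} must be inside [0,1]")


@dataclass(frozen=True)
class DoseModel:
    """Acquisition model; ``photons_i0`` is the dose proxy (higher = cleaner).

    ``mu_per_pixel`` converts the [0,1] image values into attenuation per
    pixel of path length so transmitted fractions stay in a realistic range.
    ``mode='gaussian'`` bypasses the projection pipeline and adds white noise
    with sd ``gaussian_scale / sqrt(photons_i0)`` in the image domain.
    """

    photons_i0: float = 1e5
    n_angles: int = 120
    electronic_noise_sd: float = 0.5
    mu_per_pixel: float = 0.05
    mode: str = "sinogram"
    gaussian_scale: float = 8.0

    def validate(self) -> None:
        if self.photons_i0 <= 0:
            raise ConfigurationError("photons_i0 must be > 0")
        if self.n_angles < 2:
            raise ConfigurationError("n_angles must be >= 2")
        if self.mode not in ("sinogram", "gaussian"):
            raise ConfigurationError(f"unknown dose mode {self.mode!r}")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic clean slice in [0, 1] for a given spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cy = cx = (n - 1) / 2.0
    img = np.zeros((n, n), dtype=np.float64)

    def ellipse_mask(y0, x0, ry, rx, angle):
        ys, xs = yy - y0, xx - x0
        ca, sa = np.cos(angle), np.sin(angle)
        u = ca * xs + sa * ys
        v = -sa * xs + ca * ys
        return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0

    # body outline: large soft-tissue ellipse at the low end of the range
    body = ellipse_mask(cy, cx, 0.44 * n, 0.40 * n, 0.0)
    lo, hi = spec.intensity_range
    img[body] = lo + 0.15 * (hi - lo)

    if spec.include_lung_regions:
        for side in (-1.0, 1.0):
            mask = ellipse_mask(cy - 0.04 * n, cx + side * 0.18 * n,
                                0.24 * n, 0.13 * n, side * 0.15)
            img[mask & body] = 0.03

    for _ in range(spec.n_ellipses):
        y0 = cy + rng.uniform(-0.3, 0.3) * n
        x0 = cx + rng.uniform(-0.3, 0.3) * n
        ry = rng.uniform(0.02, 0.10) * n
        rx = rng.uniform(0.02, 0.10) * n
        angle = rng.uniform(0, np.pi)
        val = rng.uniform(lo, hi)
        mask = ellipse_mask(y0, x0, ry, rx, angle) & body
        img[mask] = val

    return np.clip(img, 0.0, 1.0).astype(np.float32)


def simulate_low_dose(clean: np.ndarray, dose: DoseModel,
                      seed: int) -> np.ndarray:
    """Degrade a clean slice through the acquisition model; deterministic per seed."""
    dose.validate()
    clean = np.asarray(clean, dtype=np.float64)
    if clean.min() < -1e-6 or clean.max() > 1.0 + 1e-6:
        raise ValueError("clean image must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    if dose.mode == "gaussian":
        sd = dose.gaussian_scale / np.sqrt(dose.photons_i0)
        noisy = clean + rng.normal(0.0, sd, size=clean.shape)
        return np.clip(noisy, 0.0, 1.0).astype(np.float32)

    n = clean.shape[0]
    theta = np.linspace(0.0, 180.0, dose.n_angles, endpoint=False)
    mu = clean * dose.mu_per_pixel
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sino = radon(mu, theta=theta, circle=False)
    expected = dose.photons_i0 * np.exp(-sino)
    counts = rng.poisson(expected).astype(np.float64)
    if dose.electronic_noise_sd > 0:
        counts = counts + rng.normal(0.0, dose.electronic_noise_sd,
                                     size=counts.shape)
    counts = np.maximum(counts, 1.0)
    sino_noisy = -np.log(counts / dose.photons_i0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = iradon(sino_noisy, theta=theta, circle=False,
                     filter_name="ramp", output_size=n)
    rec = rec / dose.mu_per_pixel
    return np.clip(rec, 0.0, 1.0).astype(np.float32)


def extract_patches(image: np.ndarray, patch_size: int,
                    stride: int) -> list[np.ndarray]:
    """All patches at offsets {0, stride, 2*stride, ...} that fit; row-major."""
    h, w = image.shape[-2:]
    if patch_size > h or patch_size > w:
        raise ValueError(
            f"patch size {patch_size} exceeds image size {h}x{w}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    patches = []
    for r in range(0, h - patch_size + 1, stride):
        for c in range(0, w - patch_size + 1, stride):
            patches.append(np.ascontiguousarray(
                image[r:r + patch_size, c:c + patch_size]))
    return patches


@dataclass
class EvaluationSplit:
    """Held-out noisy/clean pairs, kept away from the training interface."""

    noisy: list[np.ndarray]
    clean: list[np.ndarray]
    paired_index: dict[int, int]


@dataclass
class PatchDataset:
    """Unpaired training patches plus an isolated evaluation split.

    Training consumers must use only :meth:`training_batches` (or the raw
    ``domain_x`` / ``domain_y`` lists); the paired evaluation split lives in
    ``evaluation`` and is never touched by the training iterator.
    """

    domain_x: list[np.ndarray]
    domain_y: list[np.ndarray]
    patch_size: int
    stride: int
    evaluation: EvaluationSplit | None = None
    manifest: list[dict] = field(default_factory=list)

    def training_batches(self, rng: np.random.Generator, n_steps: int):
        """Yield ``n_steps`` unpaired (x, y) patch pairs, independently shuffled."""
        nx, ny = len(self.domain_x), len(self.domain_y)
        if nx == 0 or ny == 0:
            raise ValueError("both domains must be non-empty")
        ix = iy = 0
        order_x = rng.permutation(nx)
        order_y = rng.permutation(ny)
        for _ in range(n_steps):
            if ix == nx:
                order_x, ix = rng.permutation(nx), 0
            if iy == ny:
                order_y, iy = rng.permutation(ny), 0
            yield self.domain_x[order_x[ix]], self.domain_y[order_y[iy]]
            ix += 1
            iy += 1


def build_unpaired_dataset(n_subjects_x: int, n_subjects_y: int,
                           slices_per_subject: int, dose: DoseModel,
                           patching: tuple[int, int], seed: int,
                           image_size: int = 512,
                           n_eval_slices: int = 1,
                           phantom_spec: PhantomSpec | None = None
                           ) -> PatchDataset:
    """Build unpaired domains from disjoint phantom cohorts.

    Domain X: low-dose simulations of cohort-X subjects. Domain Y: clean
    slices of a disjoint cohort. ``n_eval_slices`` extra cohort-X slices are
    simulated and kept, with their clean counterparts, in the evaluation
    split only.
    """
    if n_subjects_x < 1 or n_subjects_y < 1 or slices_per_subject < 1:
        raise ConfigurationError("subject and slice counts must be >= 1")
    patch_size, stride = patching
    rng = np.random.default_rng(seed)
    base = phantom_spec or PhantomSpec(image_size=image_size)
    base = replace(base, image_size=image_size)

    # subject ids: X cohort 0..nx-1, Y cohort nx..nx+ny-1 -> disjoint by
    # construction; phantom seeds derive from (dataset seed, subject, slice)
    def slice_image(subject: int, slice_id: int) -> np.ndarray:
        s = (seed * 1_000_003 + subject * 7919 + slice_id * 104729) % (2**31)
        return make_phantom(replace(base, seed=s))

    domain_x: list[np.ndarray] = []
    domain_y: list[np.ndarray] = []
    manifest: list[dict] = []
    for subj in range(n_subjects_x):
        for sl in range(slices_per_subject):
            clean = slice_image(subj, sl)
            noisy = simulate_low_dose(
                clean, dose, seed=int(rng.integers(0, 2**31)))
            for k, p in enumerate(extract_patches(noisy, patch_size, stride)):
                domain_x.append(p)
                manifest.append({"domain": "X", "subject": subj,
                                 "slice": sl, "patch": k})
    for subj in range(n_subjects_x, n_subjects_x + n_subjects_y):
        for sl in range(slices_per_subject):
            clean = slice_image(subj, sl)
            for k, p in enumerate(extract_patches(clean, patch_size, stride)):
                domain_y.append(p)
                manifest.append({"domain": "Y", "subject": subj,
                                 "slice": sl, "patch": k})

    # held-out paired split from fresh cohort-X style slices
    ev_noisy: list[np.ndarray] = []
    ev_clean: list[np.ndarray] = []
    for sl in range(n_eval_slices):
        clean = slice_image(-1, sl + 1)
        noisy = simulate_low_dose(clean, dose,
                                  seed=int(rng.integers(0, 2**31)))
        ev_noisy.extend(extract_patches(noisy, patch_size, stride))
        ev_clean.extend(extract_patches(clean, patch_size, stride))
    evaluation = EvaluationSplit(
        noisy=ev_noisy, clean=ev_clean,
        paired_index={i: i for i in range(len(ev_noisy))})

    shuffle_x = np.random.default_rng(seed + 1).permutation(len(domain_x))
    shuffle_y = np.random.default_rng(seed + 2).permutation(len(domain_y))
    domain_x = [domain_x[i] for i in shuffle_x]
    domain_y = [domain_y[i] for i in shuffle_y]
    return PatchDataset(domain_x=domain_x, domain_y=domain_y,
                        patch_size=patch_size, stride=stride,
                        evaluation=evaluation, manifest=manifest)
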