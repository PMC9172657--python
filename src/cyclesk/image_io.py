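"""Image file I/O on the normalized [0, 1] grayscale convention.

NPY round-trips losslessly; PNG/TIFF are written as 16-bit unsigned integers
(quantization error at most 1/65535 per pixel). DICOM reading is optional:
rescale slope/intercept are applied, the result is min-max normalized, and
the normalization bounds are recorded in a JSON sidecar so the HU scale can
be recovered.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image"]

_MAX16 = 65535


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel image as float32 in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        arr = np.load(path)
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single-channel 2-D array, "
                             f"got shape {arr.shape}")
        return arr.astype(np.float32)
    if suffix in (".png", ".tif", ".tiff"):
        arr = iio.imread(path)
        if arr.ndim == 3:
            raise ValueError(f"{path}: RGB input not supported; a "
                             "single-channel grayscale image is required")
        if arr.dtype == np.uint16:
            return (arr / _MAX16).astype(np.float32)
        if arr.dtype == np.uint8:
            return (arr / 255.0).astype(np.float32)
        return arr.astype(np.float32)
    if suffix in (".dcm", ".dicom"):
        return _read_dicom(path)
    raise ValueError(f"unsupported image format {suffix!r} "
                     "(PNG, TIFF, NPY or DICOM)")


def _read_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("DICOM reading requires the optional pydicom "
                          "dependency") from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ValueError(f"{path}: multi-frame DICOM is not supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr.astype(np.float64) * slope + intercept
    lo, hi = float(hu.min()), float(hu.max())
    span = hi - lo if hi > lo else 1.0
    sidecar = path.with_suffix(path.suffix + ".norm.json")
    sidecar.write_text(json.dumps({"hu_min": lo, "hu_max": hi}))
    return ((hu - lo) / span).astype(np.float32)


def write_image(img: np.ndarray, path: str | Path,
                fmt: str | None = None,
                norm_bounds: tuple[float, float] | None = None) -> Path:
    """Write a [0, 1] image; NPY is lossless, PNG/TIFF quantize to 16 bits.

    ``norm_bounds`` (for DICOM-derived images) is recorded in a JSON sidecar.
    """
    path = Path(path)
    img = np.asarray(img, np.float32)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.min() < 0.0 or img.max() > 1.0:
        warnings.warn("image values outside [0, 1] were clipped",
                      stacklevel=2)
        img = np.clip(img, 0.0, 1.0)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "npy":
        np.save(path, img)
    elif fmt in ("png", "tif", "tiff"):
        q = np.round(img.astype(np.float64) * _MAX16).astype(np.uint16)
        iio.imwrite(path, q)
    else:
        raise ValueError(f"unsupported output format {fmt!r}")
    if norm_bounds is not None:
        sidecar = path.with_suffix(path.suffix + ".norm.json")
        sidecar.write_text(json.dumps(
            {"hu_min": norm_bounds[0], "hu_max": norm_bounds[1]}))
    return path
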