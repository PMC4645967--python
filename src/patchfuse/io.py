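"""Image reading/writing with [0, 1] intensity normalization.

All pipeline math runs on float images normalized to [0, 1], which makes
the NLM filtering strength ``h`` scale-free across 8- and 16-bit inputs.
Integer images are divided by their dtype maximum on load (255 -> 1.0 for
8-bit, 65535 -> 1.0 for 16-bit); float images already in range pass
through, otherwise they are min-max rescaled.  Multi-channel inputs are
collapsed with the Rec. 601 luminance 0.299 R + 0.587 G + 0.114 B.
Single-slice DICOM is read through pydicom with rescale slope/intercept
applied before min-max normalization.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["load_image", "save_image"]

logger = logging.getLogger(__name__)

_LUMA = np.array([0.299, 0.587, 0.114])


def _normalize(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        out = arr.astype(np.float64)
        if info.min < 0 or info.max <= 0:
            lo, hi = out.min(), out.max()
            return (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)
        return out / info.max
    out = arr.astype(np.float64)
    if not np.all(np.isfinite(out)):
        raise ValueError("image contains non-finite values")
    lo, hi = out.min(), out.max()
    if lo >= 0.0 and hi <= 1.0:
        return out
    return (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)


def _load_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise ValueError(f"only single-slice DICOM is supported, got shape {arr.shape}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    lo, hi = arr.min(), arr.max()
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


def load_image(path) -> np.ndarray:
    """Read a grayscale image as a float plane normalized to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        return _load_dicom(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - message path
        raise OSError(f"cannot read image {path} ({exc})") from exc
    if arr.ndim == 3:
        if arr.shape[-1] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.shape[-1] == 3:
            arr = _normalize(arr)
            return arr @ _LUMA
        raise ValueError(f"unsupported channel layout {arr.shape} in {path}")
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image in {path}, got shape {arr.shape}")
    return _normalize(arr)


def save_image(img, path, bit_depth: int = 16) -> None:
    """Quantize a [0, 1] image to 8 or 16 bits and write PNG/TIFF.

    Out-of-range values are clipped with a logged warning; quantization
    rounds to the nearest level, so a save/load round trip is accurate to
    half a quantization step.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0.0 or img.max() > 1.0:
        logger.warning(
            "image range [%.4g, %.4g] clipped to [0, 1] on save", img.min(), img.max()
        )
        img = np.clip(img, 0.0, 1.0)
    scale = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), np.round(img * scale).astype(dtype))
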