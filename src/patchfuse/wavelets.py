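"""Multilevel 2-D discrete wavelet decomposition and reconstruction.

Thin, shape-preserving wrapper around PyWavelets.  A K-level separable DWT
splits an image into one coarse approximation band plus, per level, three
detail bands (LH, HL, HH) holding horizontal, vertical and diagonal
detail.  Symmetric (half-sample) boundary extension is used throughout;
with the extended coefficient layout PyWavelets produces, the
analysis/synthesis pair is perfectly invertible, so
``reconstruct(decompose(I))`` returns ``I`` to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = ["WaveletPyramid", "decompose", "reconstruct"]

_MODE = "symmetric"


@dataclass
class WaveletPyramid:
    """One approximation band plus per-level (LH, HL, HH) detail triples.

    ``details[k]`` holds level ``k + 1`` (finest first); ``low`` is the
    approximation at the coarsest level.  ``shape`` remembers the source
    image size so reconstruction can crop the odd-length overshoot the
    transform introduces.
    """

    low: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    wavelet_name: str
    levels: int
    shape: tuple[int, int]


def decompose(img, wavelet_name: str = "db3", levels: int = 3) -> WaveletPyramid:
    """K-level 2-D DWT of a single-channel image.

    Raises
    ------
    ValueError
        If the image is too small for the requested depth; the message
        names the maximum feasible depth for this image/wavelet pair.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    wavelet = pywt.Wavelet(wavelet_name)
    max_level = pywt.dwtn_max_level(img.shape, wavelet)
    if levels > max_level:
        raise ValueError(
            f"image of shape {img.shape} supports at most {max_level} "
            f"decomposition level(s) with wavelet '{wavelet_name}', "
            f"requested {levels}"
        )
    coeffs = pywt.wavedec2(img, wavelet, mode=_MODE, level=levels)
    low = coeffs[0]
    # pywt orders detail triples coarsest first; store finest first
    details = [tuple(np.asarray(b) for b in triple) for triple in reversed(coeffs[1:])]
    return WaveletPyramid(
        low=np.asarray(low),
        details=details,
        wavelet_name=wavelet_name,
        levels=levels,
        shape=img.shape,
    )


def reconstruct(pyr: WaveletPyramid) -> np.ndarray:
    """Inverse DWT; output is cropped to the pyramid's recorded shape."""
    coeffs = [pyr.low] + [tuple(triple) for triple in reversed(pyr.details)]
    out = pywt.waverec2(coeffs, pywt.Wavelet(pyr.wavelet_name), mode=_MODE)
    H, W = pyr.shape
    return out[:H, :W]
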