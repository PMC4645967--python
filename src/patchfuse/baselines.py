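"""Classical high-frequency fusion rules used for comparison.

Both operate per detail band inside the same wavelet framework as the
coherence-driven rule, so score differences between schemes isolate the
high-frequency rule itself.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .tensor import compute_gradient

__all__ = ["fuse_wa", "fuse_cgm"]


def _check(wA, wB) -> tuple[np.ndarray, np.ndarray]:
    wA = np.asarray(wA, dtype=np.float64)
    wB = np.asarray(wB, dtype=np.float64)
    if wA.shape != wB.shape:
        raise ValueError(f"shape mismatch: {wA.shape} vs {wB.shape}")
    return wA, wB


def fuse_wa(wA, wB) -> np.ndarray:
    """Adaptive weighted average of two detail bands.

    Local activity is the mean squared coefficient over a 3x3 window
    (mirror boundary); the per-coefficient weight is
    ``omega = sA / (sA + sB)`` with a symmetric 0.5 fallback where both
    activities vanish.  A convex combination, so the output stays within
    the per-coefficient envelope of the inputs.
    """
    wA, wB = _check(wA, wB)
    sA = ndimage.uniform_filter(wA * wA, size=3, mode="mirror")
    sB = ndimage.uniform_filter(wB * wB, size=3, mode="mirror")
    total = sA + sB
    omega = np.where(total > 0.0, np.divide(sA, np.where(total > 0.0, total, 1.0)), 0.5)
    return omega * wA + (1.0 - omega) * wB


def fuse_cgm(wA, wB) -> np.ndarray:
    """Choose-gradient-max: per coefficient, keep the source whose band
    has the larger local gradient magnitude.

    Gradients are centered differences of the band itself; ties select
    source A so the rule is deterministic.  Every output coefficient is
    exactly one of the two inputs.
    """
    wA, wB = _check(wA, wB)
    gA = compute_gradient(wA)
    gB = compute_gradient(wB)
    magA = np.hypot(gA.gx, gA.gy)
    magB = np.hypot(gB.gx, gB.gy)
    return np.where(magA >= magB, wA, wB)
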