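"""Coherence-driven wavelet fusion of two co-registered images.

Both sources are decomposed into wavelet pyramids.  The approximation
(low-frequency) bands are merged by a fixed affine average

    W_L^F = k1 * W_L^A + k2 * W_L^B,        k1 + k2 = 1,

defaulting to (k1, k2) = (0.75, 0.25).  Every detail band is merged by a
per-coefficient convex combination

    W^F = omega * W^A + (1 - omega) * W^B,
    omega = phi_A / (phi_A + phi_B),

where phi is the structure-tensor coherence (squared eigenvalue gap) of
that detail band, computed per sub-band and per level through the
patch-based tensor pipeline.  Coefficients carrying stronger oriented
structure therefore dominate the fused pyramid, which is finally inverted
to the fused image.  The two classical comparison rules (adaptive
weighted average and choose-gradient-max) plug into the same framework
via :mod:`patchfuse.baselines`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import baselines
from .tensor import (
    CoherenceMap,
    NLMParams,
    coherence,
    eigen_decompose,
    patch_structure_tensor,
)
from .wavelets import WaveletPyramid, decompose, reconstruct

__all__ = [
    "SCHEMES",
    "FusionConfig",
    "fuse_low",
    "coherence_weight",
    "fuse_high",
    "subband_coherence",
    "fuse_images",
]

SCHEMES = ("patch_tensor", "wa", "cgm")


@dataclass(frozen=True)
class FusionConfig:
    """All tunables of the fusion pipeline.

    ``scheme`` selects the high-frequency rule: ``patch_tensor``
    (coherence-weighted, the method of interest), ``wa`` (adaptive
    weighted average) or ``cgm`` (choose gradient max).  All schemes share
    the low-band rule with weights ``k1``/``k2``.  Defaults reproduce the
    reference protocol: 3-level 'db3' decomposition, 11x11 search and 5x5
    similarity windows, (k1, k2) = (0.75, 0.25).
    """

    scheme: str = "patch_tensor"
    wavelet_name: str = "db3"
    levels: int = 3
    k1: float = 0.75
    k2: float = 0.25
    nlm: NLMParams = field(default_factory=NLMParams)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not (0.0 <= self.k1 <= 1.0 and 0.0 <= self.k2 <= 1.0):
            raise ValueError("k1 and k2 must lie in [0, 1]")
        if abs(self.k1 + self.k2 - 1.0) > 1e-9:
            raise ValueError("k1 + k2 must equal 1")


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def fuse_low(wlA, wlB, k1: float = 0.75, k2: float = 0.25) -> np.ndarray:
    """Affine average of the two approximation bands."""
    wlA = np.asarray(wlA, dtype=np.float64)
    wlB = np.asarray(wlB, dtype=np.float64)
    _check_same_shape(wlA, wlB)
    return k1 * wlA + k2 * wlB


def coherence_weight(phiA, phiB) -> np.ndarray:
    """Per-coefficient weight omega = phi_A / (phi_A + phi_B) in [0, 1].

    Where both coherences vanish (neither source carries structure) the
    weight falls back to 0.5, the symmetric limit of the ratio.
    """
    phiA = np.asarray(phiA, dtype=np.float64)
    phiB = np.asarray(phiB, dtype=np.float64)
    _check_same_shape(phiA, phiB)
    if np.any(phiA < 0) or np.any(phiB < 0):
        raise ValueError("coherence maps must be nonnegative")
    total = phiA + phiB
    return np.where(total > 0.0, np.divide(phiA, np.where(total > 0.0, total, 1.0)), 0.5)


def fuse_high(wA, wB, omega) -> np.ndarray:
    """Convex combination omega * wA + (1 - omega) * wB of detail bands."""
    wA = np.asarray(wA, dtype=np.float64)
    wB = np.asarray(wB, dtype=np.float64)
    omega = np.asarray(omega, dtype=np.float64)
    _check_same_shape(wA, wB)
    _check_same_shape(wA, omega)
    return omega * wA + (1.0 - omega) * wB


def subband_coherence(band, p: NLMParams | None = None) -> CoherenceMap:
    """Coherence map of one detail band.

    Runs the full tensor pipeline — patch-based structure tensor,
    closed-form eigen-decomposition, squared eigenvalue gap — on the band
    itself, so the geometry measure lives at the band's own scale.  Bands
    smaller than the search window are handled by the window clipping
    built into the NLM filter.
    """
    if p is None:
        p = NLMParams()
    t = patch_structure_tensor(band, p)
    return coherence(eigen_decompose(t))


def _fuse_detail(bA: np.ndarray, bB: np.ndarray, cfg: FusionConfig) -> np.ndarray:
    if cfg.scheme == "patch_tensor":
        phiA = subband_coherence(bA, cfg.nlm).phi
        phiB = subband_coherence(bB, cfg.nlm).phi
        return fuse_high(bA, bB, coherence_weight(phiA, phiB))
    if cfg.scheme == "wa":
        return baselines.fuse_wa(bA, bB)
    if cfg.scheme == "cgm":
        return baselines.fuse_cgm(bA, bB)
    raise ValueError(f"unknown scheme {cfg.scheme!r}")  # pragma: no cover


def fuse_images(imgA, imgB, cfg: FusionConfig | None = None) -> np.ndarray:
    """Fuse two co-registered single-channel images.

    Inputs are expected in [0, 1] (registration is the caller's
    responsibility); the reconstruction is clipped back to [0, 1] since
    the inverse transform can overshoot the input range.
    """
    if cfg is None:
        cfg = FusionConfig()
    imgA = np.asarray(imgA, dtype=np.float64)
    imgB = np.asarray(imgB, dtype=np.float64)
    _check_same_shape(imgA, imgB)

    pyrA = decompose(imgA, cfg.wavelet_name, cfg.levels)
    pyrB = decompose(imgB, cfg.wavelet_name, cfg.levels)

    low = fuse_low(pyrA.low, pyrB.low, cfg.k1, cfg.k2)
    details = [
        tuple(_fuse_detail(bA, bB, cfg) for bA, bB in zip(tripleA, tripleB))
        for tripleA, tripleB in zip(pyrA.details, pyrB.details)
    ]
    fused = WaveletPyramid(
        low=low,
        details=details,
        wavelet_name=cfg.wavelet_name,
        levels=cfg.levels,
        shape=imgA.shape,
    )
    return np.clip(reconstruct(fused), 0.0, 1.0)
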