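"""Fusion-quality metrics.

Energy of image gradient (EOG) is a no-reference sharpness score: the
mean over pixels of the squared gradient magnitude,

    EOG(I) = (1 / HW) * sum_p (gx(p)**2 + gy(p)**2),

computed on [0, 1]-normalized intensities with the package-wide centered
gradient.  Only relative ordering between fusion schemes on the same
input pair is meaningful; absolute values depend on the normalization
convention and are not comparable across conventions.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

import numpy as np

from .tensor import compute_gradient

__all__ = ["eog", "MetricReport", "evaluate_schemes"]


def eog(img) -> float:
    """Energy of image gradient: mean squared gradient magnitude.

    Zero only for constant images; scales as ``alpha**2`` under intensity
    scaling and is invariant to transposition.
    """
    g = compute_gradient(img)
    return float(np.mean(g.gx**2 + g.gy**2))


@dataclass(frozen=True)
class MetricReport:
    """Per-scheme EOG scores for one input pair."""

    rows: tuple[tuple[str, float], ...]

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["scheme", "eog"])
        for scheme, value in self.rows:
            writer.writerow([scheme, f"{value:.6g}"])
        return buf.getvalue()

    def __str__(self) -> str:
        lines = [f"{'scheme':<14} eog"]
        lines += [f"{scheme:<14} {value:.6g}" for scheme, value in self.rows]
        return "\n".join(lines)


def evaluate_schemes(imgA, imgB, cfg=None, schemes=None) -> MetricReport:
    """Fuse one pair under each scheme and score the results with EOG."""
    from dataclasses import replace

    from .fusion import SCHEMES, FusionConfig, fuse_images

    if cfg is None:
        cfg = FusionConfig()
    if schemes is None:
        schemes = SCHEMES
    rows = []
    for scheme in schemes:
        fused = fuse_images(imgA, imgB, replace(cfg, scheme=scheme))
        rows.append((scheme, eog(fused)))
    return MetricReport(rows=tuple(rows))
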