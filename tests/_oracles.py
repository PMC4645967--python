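"""Independent brute-force oracles, written as literal loops.

These deliberately avoid the package's vectorized code paths: boundary
reflection, patch extraction and window clipping are re-derived from the
definitions with explicit index arithmetic, so agreement with the
package is a genuine cross-check rather than a tautology.
"""

import numpy as np


def reflect(i: int, n: int) -> int:
    """Mirror index (edge sample not repeated): -1 -> 1, n -> n-2."""
    while i < 0 or i >= n:
        if i < 0:
            i = -i
        else:
            i = 2 * n - 2 - i
    return i


def gradient(img):
    H, W = img.shape
    gx = np.zeros((H, W))
    gy = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            gx[i, j] = 0.5 * (img[i, reflect(j + 1, W)] - img[i, reflect(j - 1, W)])
            gy[i, j] = 0.5 * (img[reflect(i + 1, H), j] - img[reflect(i - 1, H), j])
    return gx, gy


def patch_kernel(pr: int, rho: float):
    if pr == 0:
        return np.ones((1, 1))
    g = np.zeros((2 * pr + 1, 2 * pr + 1))
    for a in range(-pr, pr + 1):
        for b in range(-pr, pr + 1):
            g[a + pr, b + pr] = np.exp(-(a * a + b * b) / (2.0 * rho * rho))
    return g / g.sum()


def patch_distance(img, X, Y, pr: int, rho: float) -> float:
    H, W = img.shape
    g = patch_kernel(pr, rho)
    d = 0.0
    for a in range(-pr, pr + 1):
        for b in range(-pr, pr + 1):
            vx = img[reflect(X[0] + a, H), reflect(X[1] + b, W)]
            vy = img[reflect(Y[0] + a, H), reflect(Y[1] + b, W)]
            d += g[a + pr, b + pr] * (vx - vy) ** 2
    return d


def nlm_weights(img, X, R: int, pr: int, h: float, rho: float):
    """Weight map over the (2R+1)^2 window, clipped to the image domain."""
    H, W = img.shape
    w = np.zeros((2 * R + 1, 2 * R + 1))
    for dy in range(-R, R + 1):
        for dx in range(-R, R + 1):
            yi, yj = X[0] + dy, X[1] + dx
            if 0 <= yi < H and 0 <= yj < W:
                d = patch_distance(img, X, (yi, yj), pr, rho)
                w[dy + R, dx + R] = np.exp(-d / (h * h))
    return w / w.sum()


def nlm_filter(plane, guide, R: int, pr: int, h: float, rho: float):
    H, W = guide.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            w = nlm_weights(guide, (i, j), R, pr, h, rho)
            acc = 0.0
            for dy in range(-R, R + 1):
                for dx in range(-R, R + 1):
                    yi, yj = i + dy, j + dx
                    if 0 <= yi < H and 0 <= yj < W:
                        acc += w[dy + R, dx + R] * plane[yi, yj]
            out[i, j] = acc
    return out


def eigen(j11, j12, j22):
    """Per-pixel generic symmetric eigensolver (numpy.linalg.eigh)."""
    H, W = j11.shape
    mu1 = np.zeros((H, W))
    mu2 = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            vals = np.linalg.eigh(np.array([[j11[i, j], j12[i, j]], [j12[i, j], j22[i, j]]]))[0]
            mu1[i, j], mu2[i, j] = vals[1], vals[0]
    return mu1, mu2


def eog(img) -> float:
    gx, gy = gradient(img)
    H, W = img.shape
    total = 0.0
    for i in range(H):
        for j in range(W):
            total += gx[i, j] ** 2 + gy[i, j] ** 2
    return total / (H * W)


def fuse_wa(wA, wB):
    H, W = wA.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            sA = sB = 0.0
            for a in (-1, 0, 1):
                for b in (-1, 0, 1):
                    ii, jj = reflect(i + a, H), reflect(j + b, W)
                    sA += wA[ii, jj] ** 2
                    sB += wB[ii, jj] ** 2
            omega = sA / (sA + sB) if sA + sB > 0 else 0.5
            out[i, j] = omega * wA[i, j] + (1 - omega) * wB[i, j]
    return out


def fuse_cgm(wA, wB):
    H, W = wA.shape
    gxA, gyA = gradient(wA)
    gxB, gyB = gradient(wB)
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            mA = np.sqrt(gxA[i, j] ** 2 + gyA[i, j] ** 2)
            mB = np.sqrt(gxB[i, j] ** 2 + gyB[i, j] ** 2)
            out[i, j] = wA[i, j] if mA >= mB else wB[i, j]
    return out
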