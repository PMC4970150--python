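"""Literal per-pixel reference implementations used as independent oracles.

These trade speed for transparency: explicit Python loops that follow the
defining formulas directly, so the vectorised production code can be checked
against them exactly.
"""

import math

import numpy as np
from scipy.signal import convolve2d

from eyeseg.frst import FRSTParams, gaussian_kernel

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = SOBEL_X.T


def sobel_loops(img: np.ndarray):
    """3x3 Sobel derivatives by explicit loops, border zeroed."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            sx = sy = 0.0
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    v = img[y + dy, x + dx]
                    sx += SOBEL_X[dy + 1, dx + 1] * v
                    sy += SOBEL_Y[dy + 1, dx + 1] * v
            gx[y, x] = sx
            gy[y, x] = sy
    return gx, gy


def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5)) if v >= 0 else int(math.ceil(v - 0.5))


def frst_naive(img: np.ndarray, params: FRSTParams) -> np.ndarray:
    """Per-pixel radial symmetry transform, straight from the definitions."""
    gx, gy = sobel_loops(img)
    h, w = gx.shape
    S = np.zeros((h, w))
    for r in params.radii:
        O = np.zeros((h, w))
        M = np.zeros((h, w))
        for y in range(h):
            for x in range(w):
                g = math.hypot(gx[y, x], gy[y, x])
                if g == 0:
                    continue
                dx = _round_half_away(gx[y, x] / g * r)
                dy = _round_half_away(gy[y, x] / g * r)
                if params.mode in ("bright", "both"):
                    px, py = x + dx, y + dy
                    if 0 <= px < w and 0 <= py < h:
                        O[py, px] += 1
                        M[py, px] += g
                if params.mode in ("dark", "both"):
                    px, py = x - dx, y - dy
                    if 0 <= px < w and 0 <= py < h:
                        O[py, px] -= 1
                        M[py, px] -= g
        o_max = np.abs(O).max()
        m_max = np.abs(M).max()
        if o_max == 0 or m_max == 0:
            continue
        o_n = O / o_max
        m_n = M / m_max
        F = np.sign(o_n) * np.abs(o_n) ** params.alpha * np.abs(m_n)
        k = gaussian_kernel(params.gaussian_sigma_factor * r)
        S += convolve2d(F, k, mode="same", boundary="fill")
    return S
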