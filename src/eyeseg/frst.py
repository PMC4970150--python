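"""Fast Radial Symmetry Transform (FRST).

A gradient-accumulation operator that highlights centres of radially
symmetric blobs.  Every pixel with a non-zero intensity gradient votes for
the pixel its gradient points at (positively-affected) and away from
(negatively-affected) at distance ``r``; votes are collected in an
orientation-count map ``O_r`` and a magnitude map ``M_r``, combined into a
radial-symmetry response and blurred with a Gaussian to spread the
contribution.  Dark blobs (an iris) are found by accumulating only the
negatively-affected votes, which makes their centres strongly negative in
the output — the detector then searches for minima.

Sign convention: the per-radius response is
``F_r = sign(Õ_r) · |Õ_r|^alpha · |M̃_r|`` where the tilde maps are the
accumulators divided by their maximum absolute value.  In a single-polarity
mode the signs of ``O_r`` and ``M_r`` agree everywhere, so this equals the
signed product ``|Õ_r|^alpha · M̃_r`` while guaranteeing that dark centres
come out negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FRSTParams",
    "gradient_field",
    "affected_offsets",
    "affected_pixels",
    "accumulate",
    "gaussian_kernel",
    "symmetry_single",
    "frst",
]

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


@dataclass(frozen=True)
class FRSTParams:
    """Transform configuration.

    radii
        disc radii (pixels) whose symmetry contributions are summed.
    alpha
        radial strictness exponent; larger values suppress elongated
        (edge-like) responses in favour of truly circular ones.
    mode
        ``"dark"`` accumulates only negatively-affected votes, ``"bright"``
        only positively-affected ones, ``"both"`` accumulates both.
    gaussian_sigma_factor
        sigma of the spreading Gaussian as a fraction of the radius.
    magnitude_floor
        fraction of the lowest gradient magnitudes ignored (0 disables).
    """

    radii: tuple[int, ...] = (4, 6, 8)
    alpha: float = 2.0
    mode: str = "dark"
    gaussian_sigma_factor: float = 0.25
    magnitude_floor: float = 0.0

    def __post_init__(self) -> None:
        if not self.radii or min(self.radii) < 1:
            raise ValueError("radii must be a non-empty sequence of r >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.mode not in ("dark", "bright", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")


def gradient_field(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """3x3 Sobel derivatives ``(gx, gy, magnitude)`` with a zeroed 1-px border."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("need a 2-D image of at least 3x3 pixels")
    # correlate (not convolve): keep the kernel orientation so gx > 0 where
    # intensity increases with x
    gx = ndimage.correlate(img, _SOBEL_X, mode="constant")
    gy = ndimage.correlate(img, _SOBEL_Y, mode="constant")
    for g in (gx, gy):
        g[0, :] = g[-1, :] = 0.0
        g[:, 0] = g[:, -1] = 0.0
    return gx, gy, np.hypot(gx, gy)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.rint rounds half-to-even; the transform spec'd here rounds half
    # away from zero so votes are placed symmetrically for +/- gradients.
    return np.trunc(x + np.copysign(0.5, x))


def affected_offsets(gx, gy, mag, r: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer (dx, dy) of the positively-affected pixel for each gradient."""
    with np.errstate(invalid="ignore", divide="ignore"):
        dx = _round_half_away(np.where(mag > 0, gx / mag * r, 0.0))
        dy = _round_half_away(np.where(mag > 0, gy / mag * r, 0.0))
    return dx.astype(np.int64), dy.astype(np.int64)


def affected_pixels(p: tuple[int, int], g: tuple[float, float], r: int):
    """Positively- and negatively-affected pixels for a single gradient.

    Returns ``None`` for a zero gradient (the pixel casts no vote).
    """
    gx, gy = float(g[0]), float(g[1])
    mag = np.hypot(gx, gy)
    if mag == 0:
        return None
    dx = int(_round_half_away(np.array(gx / mag * r)))
    dy = int(_round_half_away(np.array(gy / mag * r)))
    px, py = p
    return (px + dx, py + dy), (px - dx, py - dy)


def accumulate(
    gx: np.ndarray, gy: np.ndarray, mag: np.ndarray, r: int, mode: str = "dark",
    magnitude_floor: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vote maps ``(O_r, M_r)`` for one radius.

    Votes falling outside the image are discarded rather than clamped, so
    border cells are never over-weighted.
    """
    h, w = mag.shape
    O = np.zeros((h, w), dtype=np.float64)
    M = np.zeros((h, w), dtype=np.float64)
    active = mag > 0
    if magnitude_floor > 0 and active.any():
        thresh = np.percentile(mag[active], magnitude_floor * 100.0)
        active &= mag > thresh
    ys, xs = np.nonzero(active)
    if ys.size == 0:
        return O, M
    dx, dy = affected_offsets(gx[ys, xs], gy[ys, xs], mag[ys, xs], r)
    m = mag[ys, xs]
    if mode in ("bright", "both"):
        px, py = xs + dx, ys + dy
        ok = (px >= 0) & (px < w) & (py >= 0) & (py < h)
        np.add.at(O, (py[ok], px[ok]), 1.0)
        np.add.at(M, (py[ok], px[ok]), m[ok])
    if mode in ("dark", "both"):
        px, py = xs - dx, ys - dy
        ok = (px >= 0) & (px < w) & (py >= 0) & (py < h)
        np.add.at(O, (py[ok], px[ok]), -1.0)
        np.add.at(M, (py[ok], px[ok]), -m[ok])
    return O, M


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Unit-sum 2-D Gaussian truncated at 3 sigma (1x1 identity for sigma→0)."""
    half = int(np.floor(3.0 * sigma))
    if sigma <= 0 or half < 1:
        return np.ones((1, 1))
    x = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(x**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def symmetry_single(O: np.ndarray, M: np.ndarray, r: int, params: FRSTParams) -> np.ndarray:
    """Per-radius symmetry image ``S_r``: normalise, exponentiate, blur."""
    o_max = np.abs(O).max()
    m_max = np.abs(M).max()
    if o_max == 0 or m_max == 0:
        return np.zeros_like(O)
    o_n = O / o_max
    m_n = M / m_max
    F = np.sign(o_n) * np.abs(o_n) ** params.alpha * np.abs(m_n)
    kernel = gaussian_kernel(params.gaussian_sigma_factor * r)
    return ndimage.convolve(F, kernel, mode="constant")


def frst(img: np.ndarray, params: FRSTParams | None = None) -> np.ndarray:
    """Full transform: sum of per-radius symmetry contributions."""
    params = params or FRSTParams()
    gx, gy, mag = gradient_field(img)
    S = np.zeros_like(mag)
    for r in params.radii:
        O, M = accumulate(gx, gy, mag, r, params.mode, params.magnitude_floor)
        S += symmetry_single(O, M, r, params)
    return S
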