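"""Iris centre and radius estimation.

The centre comes from minima of the dark-mode radial symmetry transform,
filtered by appearance (the pupil must be dark), geometry (one candidate in
each half of the face, penalty above the eyebrows) and an inter-pupillary
distance prior.  The radius comes from a radial projection of horizontal
gradient magnitudes around the centre: the iris→sclera boundary is a strong
vertical edge, so the projection peaks at the true radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import FaceBox

__all__ = [
    "RadiusRange",
    "IrisCandidate",
    "IrisEstimate",
    "DetectionFailure",
    "radius_range",
    "scan_minima",
    "score_candidates",
    "select_pair",
    "refine_center",
    "radial_projection",
    "select_radius",
]

# anthropometric priors: eye width ~ face width / 5; iris width ~ 0.42 eye width
EYE_WIDTH_RATIO = 1.0 / 5.0
IRIS_TO_EYE_RATIO = 0.42


class DetectionFailure(RuntimeError):
    """Raised when a pipeline stage cannot produce an estimate."""


@dataclass(frozen=True)
class RadiusRange:
    r_min: int
    r_max: int

    def __post_init__(self) -> None:
        if not 1 <= self.r_min <= self.r_max:
            raise ValueError(f"invalid radius range [{self.r_min}, {self.r_max}]")

    @property
    def radii(self) -> tuple[int, ...]:
        return tuple(range(self.r_min, self.r_max + 1))


@dataclass
class IrisCandidate:
    x: int
    y: int
    symmetry_score: float  # signed S value at the candidate (negative = dark)
    score: float = 0.0  # appearance/geometry-weighted confidence, >= 0


@dataclass
class IrisEstimate:
    x: float
    y: float
    radius: float | None = None
    confidence: float = 0.0


def radius_range(face_width: int, tolerance: float = 0.3) -> RadiusRange:
    """Iris radius search interval from face width.

    Nominal radius R0 = 0.5 * 0.42 * (face_width / 5); the interval is
    R0 * (1 +/- tolerance), ceil/floored to integers, with a hard floor of
    2 px below which radial symmetry is meaningless.
    """
    if face_width <= 0:
        raise ValueError("face_width must be positive")
    r0 = 0.5 * IRIS_TO_EYE_RATIO * face_width * EYE_WIDTH_RATIO
    if r0 < 2.0:
        raise ValueError(
            f"face width {face_width} gives nominal iris radius {r0:.2f}px, "
            "below the 2 px floor"
        )
    lo = max(math.ceil(r0 * (1.0 - tolerance)), 2)
    hi = math.floor(r0 * (1.0 + tolerance))
    return RadiusRange(lo, max(lo, hi))


def scan_minima(S: np.ndarray, r_min: int) -> list[tuple[int, int]]:
    """Per-tile minima of the symmetry image, merged when closer than r_min.

    The image is tiled into 2*r_min windows; the minimum position of each
    tile is retained, then minima closer than r_min to each other are merged
    keeping the one with the lower S value.
    """
    S = np.asarray(S, dtype=np.float64)
    h, w = S.shape
    step = max(2 * r_min, 1)
    raw: list[tuple[float, int, int]] = []
    for y0 in range(0, h, step):
        for x0 in range(0, w, step):
            tile = S[y0 : y0 + step, x0 : x0 + step]
            j = int(np.argmin(tile))
            ty, tx = divmod(j, tile.shape[1])
            raw.append((float(tile[ty, tx]), x0 + tx, y0 + ty))
    # flat tiles give arbitrary corners; drop positions that are not below
    # the image mean response (no symmetry evidence at all)
    baseline = float(S.mean())
    raw = [c for c in raw if c[0] < baseline]
    raw.sort()  # ascending S: strongest dark response first
    kept: list[tuple[float, int, int]] = []
    for s, x, y in raw:
        if all((x - kx) ** 2 + (y - ky) ** 2 >= r_min**2 for _, kx, ky in kept):
            kept.append((s, x, y))
    return [(x, y) for _, x, y in kept]


def score_candidates(
    cands: list[tuple[int, int]],
    S: np.ndarray,
    gray: np.ndarray,
    eyebrow_row: int | None = None,
    blur_sigma: float = 2.0,
    eyebrow_penalty: float = 0.5,
) -> list[IrisCandidate]:
    """Weight symmetry minima by pupil darkness and eyebrow geometry.

    score = (-S) * (255 - blur(gray)) / 255, halved (by default) for
    candidates above the eyebrow row.  All inputs share the eye-region
    coordinate frame.
    """
    blurred = ndimage.gaussian_filter(np.asarray(gray, dtype=np.float64), blur_sigma)
    out = []
    for x, y in cands:
        s = float(S[y, x])
        darkness = (255.0 - blurred[y, x]) / 255.0
        score = max(-s, 0.0) * darkness
        if eyebrow_row is not None and y < eyebrow_row:
            score *= eyebrow_penalty
        out.append(IrisCandidate(x, y, symmetry_score=s, score=score))
    out.sort(key=lambda c: -c.score)
    return out


def select_pair(
    cands: list[IrisCandidate],
    face_w: int,
    ipd_mean: float = 0.4,
    ipd_sigma: float = 0.1,
) -> tuple[IrisEstimate, IrisEstimate]:
    """Best (left, right) candidate pair under an inter-pupillary prior.

    Candidates are split at face_w / 2; over all cross pairs the product of
    the two confidences and a Gaussian prior on the inter-pupillary distance
    (normalised by face width) is maximised.
    """
    left = [c for c in cands if c.x < face_w / 2]
    right = [c for c in cands if c.x >= face_w / 2]
    if not left or not right:
        side = "left" if not left else "right"
        raise DetectionFailure(f"no iris candidate in the {side} half of the face")
    best, best_pair = -np.inf, None
    for cl in left:
        for cr in right:
            d = math.hypot(cl.x - cr.x, cl.y - cr.y) / face_w
            prior = math.exp(-((d - ipd_mean) ** 2) / (2.0 * ipd_sigma**2))
            val = cl.score * cr.score * prior
            if val > best:
                best, best_pair = val, (cl, cr)
    cl, cr = best_pair
    return (
        IrisEstimate(cl.x, cl.y, confidence=cl.score),
        IrisEstimate(cr.x, cr.y, confidence=cr.score),
    )


def refine_center(
    gray: np.ndarray, center: tuple[float, float], r_min: int, blur_sigma: float = 2.0
) -> tuple[int, int]:
    """Constrain the centre to the dark pupil region.

    Searches a (r_min/2 x r_min/2) window around the current estimate for
    the minimum of the blurred image; ties break toward the unrefined
    centre.  The window is clipped at image borders.
    """
    h, w = gray.shape
    cx, cy = int(round(center[0])), int(round(center[1]))
    half = max(int(round(r_min / 2)) // 2, 1)  # window extent each side
    x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
    y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
    if x0 >= x1 or y0 >= y1:
        return cx, cy
    win = ndimage.gaussian_filter(np.asarray(gray, dtype=np.float64), blur_sigma)[
        y0:y1, x0:x1
    ]
    lo = win.min()
    ys, xs = np.nonzero(win == lo)
    d2 = (xs + x0 - cx) ** 2 + (ys + y0 - cy) ** 2
    j = int(np.argmin(d2))
    return int(xs[j] + x0), int(ys[j] + y0)


def radial_projection(
    gray_roi: np.ndarray,
    center: tuple[float, float],
    rng: RadiusRange,
    k: float = 20.0,
    theta_deg: tuple[float, float] = (-45.0, 45.0),
    blur_sigma: float = 2.0,
) -> np.ndarray:
    """Sum of horizontal-gradient magnitudes on circles around the centre.

    The ROI is blurred, differentiated with a Sobel kernel sensitive to
    vertical edges, and the weakest k% of the non-zero responses are zeroed
    to suppress noise.  For each candidate radius the absolute responses at
    nearest pixels (cx +/- r cos(theta), cy +/- r sin(theta)), theta sampled
    every degree within ``theta_deg``, are accumulated; samples falling
    outside the ROI contribute zero.
    """
    roi = ndimage.gaussian_filter(np.asarray(gray_roi, dtype=np.float64), blur_sigma)
    sob = np.abs(ndimage.convolve(
        roi, np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float), mode="nearest"
    ))
    nz = sob[sob > 0]
    if nz.size and k > 0:
        sob[sob < np.percentile(nz, k)] = 0.0
    h, w = sob.shape
    cx, cy = center
    thetas = np.deg2rad(np.arange(theta_deg[0], theta_deg[1] + 1e-9, 1.0))
    cs, sn = np.cos(thetas), np.sin(thetas)
    proj = np.zeros(len(rng.radii))
    for i, r in enumerate(rng.radii):
        total = 0.0
        for sgn in (1.0, -1.0):
            xs = np.rint(cx + sgn * r * cs).astype(int)
            ys = np.rint(cy + sgn * r * sn).astype(int)
            ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
            total += sob[ys[ok], xs[ok]].sum()
        proj[i] = total
    return proj


def select_radius(proj: np.ndarray, rng: RadiusRange) -> int:
    """Most prominent projection peak; ties break toward the smaller radius."""
    proj = np.asarray(proj, dtype=np.float64)
    if proj.size == 0:
        raise DetectionFailure("empty radial projection")
    if not proj.any():
        raise DetectionFailure("no gradient evidence for any candidate radius")
    return rng.radii[int(np.argmax(proj))]
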