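"""Image containers, face-proportion geometry and eyebrow-row estimation.

Images are plain numpy arrays: grayscale images are 2-D ``uint8`` arrays and
RGB images are ``(H, W, 3) uint8`` arrays with channel order R, G, B
regardless of the on-disk format.  All rectangles use the 0-based, half-open
``[x, x + w)`` convention with x growing right and y growing down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import imageio.v3 as iio

__all__ = [
    "FaceBox",
    "EyeRegion",
    "load_rgb",
    "save_image",
    "to_gray",
    "crop_face_width",
    "vertical_projection",
    "estimate_eyebrow_row",
    "eye_search_region",
]

# BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class FaceBox:
    """Axis-aligned face rectangle, half-open pixel coordinates."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"degenerate face box {self.w}x{self.h}")

    def crop(self, img: np.ndarray) -> np.ndarray:
        return img[self.y : self.y + self.h, self.x : self.x + self.w]


@dataclass(frozen=True)
class EyeRegion:
    """Horizontal band of the (cropped) face expected to contain both eyes.

    ``eyebrow_row`` is the estimated eyebrow row in the coordinates of
    ``box`` (i.e. relative to the band's own top edge).
    """

    box: FaceBox
    eyebrow_row: int


def load_rgb(path) -> np.ndarray:
    """Read a PNG/JPEG/BMP file as an (H, W, 3) uint8 RGB array."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return np.ascontiguousarray(arr.astype(np.uint8))


def save_image(path, img: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def to_gray(img: np.ndarray) -> np.ndarray:
    """BT.601 luma conversion, rounded to uint8."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    return np.rint(img.astype(np.float64) @ _LUMA).clip(0, 255).astype(np.uint8)


def crop_face_width(face: FaceBox, fraction: float = 0.70) -> FaceBox:
    """Shrink the face box horizontally to ``fraction`` of its width, centred.

    The default removes 15% of the width on each side so that hair and
    background are excluded before any projection analysis.  The left offset
    is floored and the new width rounded, both to integer pixels.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    new_w = int(round(face.w * fraction))
    if new_w < 1:
        raise ValueError("cropped face width collapses below one pixel")
    off = math.floor(face.w * (1.0 - fraction) / 2.0)
    return FaceBox(face.x + off, face.y, new_w, face.h)


def vertical_projection(img: np.ndarray) -> np.ndarray:
    """Per-row intensity sums (length = image height)."""
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    return img.sum(axis=1, dtype=np.float64)


def estimate_eyebrow_row(
    proj: np.ndarray, smoothing: int = 5, min_prominence: float = 0.1
) -> int:
    """First prominent valley of the smoothed row-sum projection.

    The projection is smoothed with a centred moving average of ``smoothing``
    rows, then scanned top-down for the first strict local minimum (a
    projection valley — the dark eyebrow band depresses its row sums) whose
    depth relative to the surrounding maxima is at least ``min_prominence``
    of the projection's full range; shallower ripples are pixel noise, not a
    facial feature.  On a plateau the topmost index wins; if no qualifying
    valley exists the global minimum row is returned.
    """
    proj = np.asarray(proj, dtype=np.float64)
    if proj.size < 3:
        raise ValueError("projection too short")
    if smoothing > 1:
        from scipy.ndimage import uniform_filter1d

        # nearest-edge padding: zero padding would fake valleys at the ends
        sm = uniform_filter1d(proj, size=min(int(smoothing), proj.size), mode="nearest")
    else:
        sm = proj
    span = sm.max() - sm.min()
    interior = (sm[1:-1] < sm[:-2]) & (sm[1:-1] <= sm[2:])
    for i in np.flatnonzero(interior) + 1:
        depth = min(sm[:i].max(), sm[i + 1 :].max()) - sm[i]
        if span == 0 or depth >= min_prominence * span:
            return int(i)
    return int(np.argmin(sm))


def eye_search_region(
    face: FaceBox,
    gray: np.ndarray | None = None,
    band: tuple[float, float] = (0.20, 0.55),
    smoothing: int = 5,
) -> EyeRegion:
    """Upper facial band expected to contain the eyes, plus its eyebrow row.

    ``band`` gives the top/bottom of the band as fractions of the face
    height; the defaults follow standard facial-proportion priors.  If a
    grayscale image (full frame, same coordinates as ``face``) is supplied,
    the eyebrow row is estimated from the band's vertical projection,
    otherwise row 0 of the band is reported.
    """
    lo, hi = band
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("band fractions must satisfy 0 <= lo < hi <= 1")
    top = face.y + int(round(lo * face.h))
    bot = face.y + int(round(hi * face.h))
    if bot - top < 1:
        raise ValueError("degenerate eye band")
    box = FaceBox(face.x, top, face.w, bot - top)
    row = 0
    if gray is not None:
        proj = vertical_projection(box.crop(gray))
        row = estimate_eyebrow_row(proj, smoothing=smoothing)
    return EyeRegion(box=box, eyebrow_row=row)
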