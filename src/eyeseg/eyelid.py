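"""Two-parabola eyelid model fitted by Monte Carlo sampling.

The external eye shape is two intersecting parabolas, one per eyelid,
generated from a 12-value control-point vector expressed relative to the
iris centre.  Candidate shapes are drawn uniformly from anthropometric
bounds proportional to the iris radius, scored against a sclera-probability
map (the eyelid curve should separate high-probability sclera pixels just
inside it from low-probability skin/lash pixels just outside), and the
fittest fraction votes for the solution with fitness-proportional weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "EyeShape",
    "Parabola",
    "Hypothesis",
    "MatchParams",
    "ShapeBounds",
    "parabola_from_points",
    "shape_to_parabolas",
    "band_pixels",
    "score_hypothesis",
    "generate_hypotheses",
    "vote_shape",
    "eye_corners",
    "shape_mask",
    "segment_eye",
]

_COORD_NAMES = (
    "cx", "cy", "tx", "ty", "bx", "by",
    "tlx", "tly", "trx", "try_", "bly", "bry",
)


@dataclass(frozen=True)
class EyeShape:
    """Control-point vector of the two-parabola eye model.

    (cx, cy) is the iris centre in absolute image coordinates; every other
    value is relative to it.  (tx, ty) / (bx, by) are the top/bottom eyelid
    mid-points; (tlx, tly) and (trx, try_) are the left/right control points
    of the top parabola; bly and bry are y-offsets added to tly/try_ to
    place the bottom parabola's outer control points at the same x.
    """

    cx: float
    cy: float
    tx: float
    ty: float
    bx: float
    by: float
    tlx: float
    tly: float
    trx: float
    try_: float
    bly: float
    bry: float

    def __post_init__(self) -> None:
        if not (self.tlx < self.tx < self.trx):
            raise ValueError("control points must satisfy tlx < tx < trx")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _COORD_NAMES], dtype=np.float64)

    @classmethod
    def from_vector(cls, v) -> "EyeShape":
        v = np.asarray(v, dtype=np.float64)
        if v.shape != (12,):
            raise ValueError("shape vector must have 12 values")
        return cls(**dict(zip(_COORD_NAMES, map(float, v))))

    def translated(self, dx: float, dy: float) -> "EyeShape":
        return replace(self, cx=self.cx + dx, cy=self.cy + dy)


@dataclass(frozen=True)
class Parabola:
    """y = a x^2 + b x + c in absolute pixel coordinates."""

    a: float
    b: float
    c: float

    def __call__(self, x):
        x = np.asarray(x, dtype=np.float64)
        return self.a * x**2 + self.b * x + self.c


@dataclass
class Hypothesis:
    shape: EyeShape
    omega: float = 0.0


@dataclass(frozen=True)
class MatchParams:
    """Hypothesis scoring and voting configuration.

    alpha/beta weigh the inner (sclera) and outer (skin) probability bands
    and must sum to 1; delta is the band depth in pixels; n_hypotheses and
    top_fraction control the Monte Carlo sample and the voting pool.
    """

    alpha: float = 0.5
    beta: float = 0.5
    delta: int = 5
    n_hypotheses: int = 200
    top_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("alpha + beta must equal 1")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.n_hypotheses < 1 or not 0 < self.top_fraction <= 1:
            raise ValueError("invalid sampling parameters")


#: Uniform sampling bounds for each relative coordinate, as multiples of the
#: iris radius R.  Chosen from eye anthropometry: the palpebral fissure is
#: roughly 2.5-3 iris radii to each side of the centre and 1-2 radii tall.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "tx": (-0.5, 0.5),
    "ty": (-2.2, -0.8),
    "bx": (-0.5, 0.5),
    "by": (0.8, 2.2),
    "tlx": (-3.0, -1.2),
    "tly": (-1.2, 0.6),
    "trx": (1.2, 3.0),
    "try_": (-1.2, 0.6),
    "bly": (0.2, 2.5),
    "bry": (0.2, 2.5),
}

ShapeBounds = dict[str, tuple[float, float]]


def parabola_from_points(p1, p2, p3) -> Parabola:
    """Unique interpolating parabola through three points with distinct x."""
    xs = np.array([p1[0], p2[0], p3[0]], dtype=np.float64)
    ys = np.array([p1[1], p2[1], p3[1]], dtype=np.float64)
    if len(np.unique(xs)) != 3:
        raise ValueError("points must have distinct x coordinates")
    A = np.vander(xs, 3)  # columns x^2, x, 1
    a, b, c = np.linalg.solve(A, ys)
    return Parabola(float(a), float(b), float(c))


def shape_to_parabolas(shape: EyeShape) -> tuple[Parabola, Parabola]:
    """Absolute-coordinate top and bottom eyelid parabolas."""
    cx, cy = shape.cx, shape.cy
    top = parabola_from_points(
        (cx + shape.tlx, cy + shape.tly),
        (cx + shape.tx, cy + shape.ty),
        (cx + shape.trx, cy + shape.try_),
    )
    bottom = parabola_from_points(
        (cx + shape.tlx, cy + shape.tly + shape.bly),
        (cx + shape.bx, cy + shape.by),
        (cx + shape.trx, cy + shape.try_ + shape.bry),
    )
    return top, bottom


def band_pixels(
    parabola: Parabola,
    side: str,
    delta: int,
    x_range: tuple[int, int],
    image_shape: tuple[int, int] | None = None,
    eyelid: str = "top",
) -> np.ndarray:
    """Integer pixels at vertical offsets 1..delta from the curve.

    ``side`` is ``"inner"`` (toward the eye interior: below a top eyelid,
    above a bottom eyelid) or ``"outer"``.  Returns an (N, 2) array of
    (x, y); pixels outside ``image_shape`` (h, w) are dropped.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    down = (eyelid == "top") == (side == "inner")
    sgn = 1 if down else -1
    xs = np.arange(x_range[0], x_range[1] + 1)
    ys0 = np.rint(parabola(xs)).astype(int)
    ds = np.arange(1, delta + 1)
    X = np.repeat(xs, len(ds))
    Y = (ys0[:, None] + sgn * ds[None, :]).ravel()
    pts = np.stack([X, Y], axis=-1)
    if image_shape is not None:
        h, w = image_shape
        ok = (X >= 0) & (X < w) & (Y >= 0) & (Y < h)
        pts = pts[ok]
    if len(pts) == 0:
        raise ValueError("band has no pixels inside the image")
    return pts


def _band_mean(prob_map: np.ndarray, pts: np.ndarray) -> tuple[float, int]:
    return float(prob_map[pts[:, 1], pts[:, 0]].sum()), len(pts)


def score_hypothesis(
    prob_map: np.ndarray,
    shape: EyeShape,
    params: MatchParams,
    x_range: tuple[int, int] | None = None,
) -> float:
    """Band-contrast fitness of a shape against the sclera-probability map.

    omega = (alpha * mean(inner) - beta * mean(outer)) / (alpha + beta),
    pooling the inner and outer bands of both eyelid parabolas.  Positive
    when the curve separates bright sclera inside from dark skin outside;
    bounded by [-1, 1] for probability maps.
    """
    top, bottom = shape_to_parabolas(shape)
    h, w = prob_map.shape
    if x_range is None:
        half = max(abs(shape.tlx), abs(shape.trx))
        x_range = (int(math.floor(shape.cx - half)), int(math.ceil(shape.cx + half)))
    x_range = (max(x_range[0], 0), min(x_range[1], w - 1))
    if x_range[0] > x_range[1]:
        raise ValueError("hypothesis lies outside the probability map")
    sums = {"inner": 0.0, "outer": 0.0}
    counts = {"inner": 0, "outer": 0}
    for eyelid, par in (("top", top), ("bottom", bottom)):
        for side in ("inner", "outer"):
            pts = band_pixels(par, side, params.delta, x_range, (h, w), eyelid)
            s, n = _band_mean(prob_map, pts)
            sums[side] += s
            counts[side] += n
    mean_in = sums["inner"] / counts["inner"]
    mean_out = sums["outer"] / counts["outer"]
    return (params.alpha * mean_in - params.beta * mean_out) / (
        params.alpha + params.beta
    )


def generate_hypotheses(
    center: tuple[float, float],
    iris_radius: float,
    params: MatchParams,
    bounds: ShapeBounds | None = None,
    rng: np.random.Generator | None = None,
) -> list[Hypothesis]:
    """Uniform shape samples over bounds proportional to the iris radius."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    names = [n for n in _COORD_NAMES if n not in ("cx", "cy")]
    lo = np.array([bounds[n][0] for n in names]) * iris_radius
    hi = np.array([bounds[n][1] for n in names]) * iris_radius
    if np.any(lo > hi):
        raise ValueError("invalid sampling bounds")
    out: list[Hypothesis] = []
    while len(out) < params.n_hypotheses:
        v = rng.uniform(lo, hi)
        vals = dict(zip(names, v))
        if not (vals["tlx"] < vals["tx"] < vals["trx"]):
            continue  # resample ordering violations
        out.append(
            Hypothesis(EyeShape(cx=center[0], cy=center[1], **vals))
        )
    return out


def vote_shape(hypotheses: list[Hypothesis], params: MatchParams, eps: float = 1e-6) -> EyeShape:
    """Fitness-weighted average of the top fraction of hypotheses.

    The selected scores are shifted by the minimum selected omega (floored
    at ``eps``) so weights are non-negative even when omega itself is; the
    result is the per-coordinate weighted mean, a convex combination of the
    selected control points.
    """
    if not hypotheses:
        raise ValueError("no hypotheses to vote over")
    ranked = sorted(hypotheses, key=lambda hyp: -hyp.omega)
    n_sel = max(1, math.ceil(params.top_fraction * len(ranked)))
    sel = ranked[:n_sel]
    omegas = np.array([hyp.omega for hyp in sel])
    w = np.maximum(omegas - omegas.min(), eps)
    if not np.isfinite(w).all() or w.sum() <= 0:
        return sel[0].shape
    vecs = np.stack([hyp.shape.as_vector() for hyp in sel])
    avg = (w[:, None] * vecs).sum(axis=0) / w.sum()
    return EyeShape.from_vector(avg)


def eye_corners(top: Parabola, bottom: Parabola) -> tuple[tuple[float, float], tuple[float, float]]:
    """Intersections of the two eyelid parabolas, left then right."""
    a = top.a - bottom.a
    b = top.b - bottom.b
    c = top.c - bottom.c
    if abs(a) < 1e-12:
        if abs(b) < 1e-12:
            raise ValueError("parabolas do not intersect in two points")
        roots = np.array([-c / b])
    else:
        disc = b * b - 4.0 * a * c
        if disc <= 0:
            raise ValueError("parabolas do not intersect in two points")
        sq = math.sqrt(disc)
        roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    if len(roots) < 2:
        raise ValueError("parabolas do not intersect in two points")
    roots = np.sort(roots)
    return (float(roots[0]), float(top(roots[0]))), (float(roots[1]), float(top(roots[1])))


def shape_mask(shape: EyeShape, image_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels between the two parabolas and the corner x's."""
    top, bottom = shape_to_parabolas(shape)
    h, w = image_shape
    try:
        (lx, _), (rx, _) = eye_corners(top, bottom)
    except ValueError:
        lx, rx = shape.cx + shape.tlx, shape.cx + shape.trx
    xs = np.arange(w)
    yy, xx = np.mgrid[0:h, 0:w]
    ty = top(xs)[None, :]
    by = bottom(xs)[None, :]
    return (yy >= ty) & (yy <= by) & (xx >= lx) & (xx <= rx)


def segment_eye(
    prob_map: np.ndarray,
    center: tuple[float, float],
    iris_radius: float,
    params: MatchParams | None = None,
    bounds: ShapeBounds | None = None,
    rng: np.random.Generator | None = None,
):
    """Full Monte Carlo eye-shape loop: sample, score, vote, corners, mask.

    Returns ``(shape, (left_corner, right_corner), mask)``.
    """
    params = params or MatchParams()
    hyps = generate_hypotheses(center, iris_radius, params, bounds, rng)
    x_range = (
        int(math.floor(center[0] - 3.0 * iris_radius)),
        int(math.ceil(center[0] + 3.0 * iris_radius)),
    )
    for hyp in hyps:
        hyp.omega = score_hypothesis(prob_map, hyp.shape, params, x_range)
    shape = vote_shape(hyps, params)
    top, bottom = shape_to_parabolas(shape)
    try:
        corners = eye_corners(top, bottom)
    except ValueError:
        lx, rx = x_range
        corners = ((float(lx), float(top(lx))), (float(rx), float(top(rx))))
    mask = shape_mask(shape, prob_map.shape)
    return shape, corners, mask
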