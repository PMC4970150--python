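"""Parametric renderer of frontal eye and face images with exact ground truth.

The renderer emulates the structure the detector exploits: a skin
background, an off-white sclera region bounded by two eyelid parabolas, a
dark circular iris with a darker pupil, dark eyebrow bands, additive
Gaussian noise and an optional specular highlight.  Every render returns
pixel-exact annotations and masks (no anti-aliasing by default), so
parameter-recovery tests are well-posed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotation import AnnotationDoc, EyeAnnotation, write_annotation
from .eyelid import EyeShape, eye_corners, shape_mask, shape_to_parabolas
from .imaging import FaceBox, save_image

__all__ = [
    "DEFAULT_COLORS",
    "EyeRenderSpec",
    "FaceRenderSpec",
    "default_eye_shape",
    "render_eye",
    "render_face",
    "generate_dataset",
]

DEFAULT_COLORS = {
    "skin": (205, 170, 140),
    "sclera": (235, 230, 225),
    "iris": (60, 80, 40),
    "pupil": (15, 15, 15),
    "eyebrow": (70, 50, 35),
    "highlight": (250, 250, 250),
}

#: Canonical eyelid control points in multiples of the iris radius; mid-range
#: of the hypothesis sampling bounds so a fully open, unoccluded eye results.
_SHAPE_TEMPLATE = {
    "tx": 0.0, "ty": -1.5, "bx": 0.0, "by": 1.5,
    "tlx": -2.1, "tly": -0.3, "trx": 2.1, "try_": -0.3,
    "bly": 1.2, "bry": 1.2,
}


def default_eye_shape(cx: float, cy: float, iris_radius: float, **overrides) -> EyeShape:
    """Anthropometric eyelid shape scaled by the iris radius."""
    vals = {k: v * iris_radius for k, v in _SHAPE_TEMPLATE.items()}
    vals.update(overrides)
    return EyeShape(cx=cx, cy=cy, **vals)


@dataclass(frozen=True)
class EyeRenderSpec:
    shape: EyeShape  # ground-truth eyelid shape, absolute coordinates
    iris_radius: float
    pupil_radius: float
    canvas: tuple[int, int]  # (h, w)
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    noise_sigma: float = 0.0
    highlight: tuple[float, float, float] | None = None  # (x, y, radius)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pupil_radius < self.iris_radius:
            raise ValueError("need 0 < pupil_radius < iris_radius")


@dataclass(frozen=True)
class FaceRenderSpec:
    face_w: int = 320
    face_h: int = 320
    ipd_ratio: float = 0.4  # inter-pupillary distance / face width
    eye_y_ratio: float = 0.42  # eye-centre row / face height
    iris_radius: float | None = None  # default: 0.42 * (face_w / 5) / 2
    pupil_ratio: float = 0.4  # pupil radius / iris radius
    eye_shape_overrides: dict = field(default_factory=dict)
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    noise_sigma: float = 2.0
    seed: int = 0


def _disk_mask(h: int, w: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def _paint_eye(
    img: np.ndarray, spec: EyeRenderSpec
) -> tuple[EyeAnnotation, dict[str, np.ndarray]]:
    """Paint one eye onto ``img`` in place; return its annotation and masks."""
    h, w = img.shape[:2]
    shape = spec.shape
    eye = shape_mask(shape, (h, w))
    if not eye.any():
        raise ValueError("eye shape is not renderable inside the canvas")
    c = spec.colors
    img[eye] = c["sclera"]
    iris = _disk_mask(h, w, shape.cx, shape.cy, spec.iris_radius) & eye
    img[iris] = c["iris"]
    pupil = _disk_mask(h, w, shape.cx, shape.cy, spec.pupil_radius) & eye
    img[pupil] = c["pupil"]
    if spec.highlight is not None:
        hx, hy, hr = spec.highlight
        img[_disk_mask(h, w, hx, hy, hr) & eye] = c["highlight"]
    top, bottom = shape_to_parabolas(shape)
    left, right = eye_corners(top, bottom)
    ann = EyeAnnotation(
        pupil_center=(shape.cx, shape.cy),
        iris_radius=float(spec.iris_radius),
        inner_corner=right,  # for a left-side eye; caller may relabel
        outer_corner=left,
        top_eyelid_mid=(shape.cx + shape.tx, shape.cy + shape.ty),
        bottom_eyelid_mid=(shape.cx + shape.bx, shape.cy + shape.by),
        shape=[float(v) for v in shape.as_vector()],
    )
    return ann, {"eye": eye, "sclera": eye & ~iris, "iris": iris, "pupil": pupil}


def _add_noise(img: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma <= 0:
        return img
    noisy = img.astype(np.float64) + rng.normal(0.0, sigma, img.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def render_eye(spec: EyeRenderSpec):
    """Render a single periocular image.

    Returns ``(rgb_image, annotation, masks)`` where masks is a dict of
    boolean arrays for the eye opening, sclera, iris and pupil regions.
    """
    h, w = spec.canvas
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = spec.colors["skin"]
    ann, masks = _paint_eye(img, spec)
    img = _add_noise(img, spec.noise_sigma, np.random.default_rng(spec.seed))
    return img, ann, masks


def render_face(spec: FaceRenderSpec):
    """Render a frontal face with two eyes and eyebrow bands.

    Returns ``(rgb_image, AnnotationDoc, FaceBox, masks)``; masks maps
    "left"/"right" to the per-eye mask dicts.  "left"/"right" are image
    left/right (the subject's right/left eye respectively).
    """
    w, h = spec.face_w, spec.face_h
    R = spec.iris_radius
    if R is None:
        R = 0.42 * (w / 5.0) / 2.0
    cy = spec.eye_y_ratio * h
    half_ipd = spec.ipd_ratio * w / 2.0
    centers = {"left": (w / 2.0 - half_ipd, cy), "right": (w / 2.0 + half_ipd, cy)}
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = spec.colors["skin"]
    doc = AnnotationDoc(image=None, meta={"face_w": w, "face_h": h})
    masks: dict[str, dict[str, np.ndarray]] = {}
    for side, (cx, cyy) in centers.items():
        shape = default_eye_shape(cx, cyy, R, **spec.eye_shape_overrides)
        eye_spec = EyeRenderSpec(
            shape=shape,
            iris_radius=R,
            pupil_radius=max(spec.pupil_ratio * R, 1.0),
            canvas=(h, w),
            colors=spec.colors,
            noise_sigma=0.0,
        )
        ann, m = _paint_eye(img, eye_spec)
        if side == "right":  # nose is to the image-left of a right-side eye
            ann.inner_corner, ann.outer_corner = ann.outer_corner, ann.inner_corner
        doc.eyes[side] = ann
        masks[side] = m
        # eyebrow band above the eye
        bx0 = int(round(cx - 3.0 * R))
        bx1 = int(round(cx + 3.0 * R))
        by0 = int(round(cyy - 3.2 * R))
        by1 = int(round(cyy - 2.4 * R))
        img[max(by0, 0) : max(by1, 0), max(bx0, 0) : bx1] = spec.colors["eyebrow"]
    img = _add_noise(img, spec.noise_sigma, np.random.default_rng(spec.seed))
    return img, doc, FaceBox(0, 0, w, h), masks


def face_spec_for_difficulty(
    difficulty: str, seed: int, base: FaceRenderSpec | None = None
) -> FaceRenderSpec:
    """Jittered render spec for one corpus image.

    ``clean`` varies geometry mildly at low noise; ``noisy`` raises the
    pixel noise; ``occluded`` additionally drops the top eyelid so it
    covers the upper iris (semi-closed eyes).
    """
    rng = np.random.default_rng(seed)
    base = base or FaceRenderSpec()
    overrides = dict(base.eye_shape_overrides)
    r0 = base.iris_radius if base.iris_radius is not None else 0.42 * base.face_w / 10.0
    R = r0 * rng.uniform(0.9, 1.1)
    spec = replace(
        base,
        ipd_ratio=base.ipd_ratio + rng.uniform(-0.02, 0.02),
        eye_y_ratio=base.eye_y_ratio + rng.uniform(-0.02, 0.02),
        iris_radius=R,
        seed=seed,
    )
    if difficulty == "clean":
        return replace(spec, noise_sigma=2.0, eye_shape_overrides=overrides)
    if difficulty == "noisy":
        return replace(spec, noise_sigma=12.0, eye_shape_overrides=overrides)
    if difficulty == "occluded":
        overrides["ty"] = -0.2 * R  # lid edge covers the upper pupil
        return replace(spec, noise_sigma=2.0, eye_shape_overrides=overrides)
    raise ValueError(f"unknown difficulty {difficulty!r}")


def training_pixels(
    n_images: int = 4, seed: int = 0, patch: int = 10, n_pos: int = 25, n_neg: int = 30
):
    """Labeled sclera / non-sclera pixel pools from rendered faces.

    Emulates hand-cut training patches: ``n_pos`` roughly patch x patch
    pixel draws from the sclera masks and ``n_neg`` from everything else
    (skin, iris, eyebrows), pooled over ``n_images`` renders.  Returns
    ``(pos_pixels, neg_pixels)`` as (N, 3) uint8 arrays.
    """
    rng = np.random.default_rng(seed)
    pos_parts, neg_parts = [], []
    per_patch = patch * patch
    for i in range(n_images):
        img, _, _, masks = render_face(FaceRenderSpec(seed=seed + 1000 + i))
        sclera = masks["left"]["sclera"] | masks["right"]["sclera"]
        eye = masks["left"]["eye"] | masks["right"]["eye"]
        pos_idx = np.flatnonzero(sclera)
        neg_idx = np.flatnonzero(~eye)
        flat = img.reshape(-1, 3)
        k_pos = min(n_pos * per_patch // n_images + 1, len(pos_idx))
        k_neg = min(n_neg * per_patch // n_images + 1, len(neg_idx))
        pos_parts.append(flat[rng.choice(pos_idx, k_pos, replace=False)])
        neg_parts.append(flat[rng.choice(neg_idx, k_neg, replace=False)])
    return np.vstack(pos_parts), np.vstack(neg_parts)


def generate_dataset(out_dir, n: int, difficulty: str = "clean", seed: int = 0):
    """Write a reproducible corpus of face renders with annotations.

    Per image: ``face_XXX.png``, ``face_XXX.json`` and the two eye masks as
    PNGs.  Returns the list of image paths.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(n):
        spec = face_spec_for_difficulty(difficulty, seed + i)
        img, doc, _, masks = render_face(spec)
        stem = f"face_{i:03d}"
        img_path = out / f"{stem}.png"
        save_image(img_path, img)
        doc.image = img_path.name
        doc.meta["difficulty"] = difficulty
        write_annotation(out / f"{stem}.json", doc)
        for side in ("left", "right"):
            save_image(
                out / f"{stem}_{side}_mask.png",
                masks[side]["eye"].astype(np.uint8) * 255,
            )
        paths.append(img_path)
    manifest = {
        "n": n,
        "difficulty": difficulty,
        "seed": seed,
        "sha256": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in paths
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
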