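"""End-to-end detection pipeline.

Given an RGB frame and a face box (from any external detector), runs:
crop → eye band + eyebrow row → dark-mode radial symmetry transform →
candidate minima → appearance/geometry scoring → pair selection → pupil
refinement → radial-projection radius → sclera probability map → Monte
Carlo eyelid fit → corners, and emits one annotation per eye plus a
structured per-stage log.
"""

from __future__ import annotations

import time
from dataclasses import replace

import numpy as np

from . import iris
from .frst import FRSTParams, frst as frst_transform
from .annotation import AnnotationDoc, EyeAnnotation
from .config import PipelineConfig
from .eyelid import segment_eye, shape_to_parabolas
from .imaging import FaceBox, crop_face_width, eye_search_region, to_gray
from .sclera import ScleraLUT, probability_map

__all__ = ["detect_pipeline"]


def _stage(log: dict, name: str, t0: float, **info) -> float:
    t1 = time.perf_counter()
    log[name] = {"ms": round((t1 - t0) * 1e3, 3), **info}
    return t1


def detect_pipeline(
    img: np.ndarray,
    face: FaceBox,
    lut: ScleraLUT | None = None,
    cfg: PipelineConfig | None = None,
) -> tuple[AnnotationDoc, dict]:
    """Detect both eyes; returns ``(AnnotationDoc, stage_log)``.

    Coordinates in the annotations are full-image.  Eyelid fitting needs a
    sclera LUT; without one (or with ``cfg.fit_shape`` off) the shape and
    corner fields stay ``None``.
    """
    cfg = cfg or PipelineConfig()
    log: dict = {"config_hash": cfg.hash(), "seed": cfg.seed}
    t = time.perf_counter()

    gray = to_gray(img)
    cropped = crop_face_width(face, cfg.crop_fraction)
    region = eye_search_region(cropped, gray, cfg.eye_band, cfg.projection_smoothing)
    t = _stage(log, "eye_region", t, eyebrow_row=region.eyebrow_row)

    rr = iris.radius_range(face.w, cfg.radius_tolerance)
    region_gray = region.box.crop(gray)
    params = FRSTParams(
        radii=rr.radii,
        alpha=cfg.frst_alpha,
        mode="dark",
        gaussian_sigma_factor=cfg.frst_sigma_factor,
    )
    S = frst_transform(region_gray, params)
    t = _stage(log, "frst", t, radii=[rr.r_min, rr.r_max])

    cands = iris.scan_minima(S, rr.r_min)
    scored = iris.score_candidates(
        cands, S, region_gray, region.eyebrow_row, cfg.blur_sigma, cfg.eyebrow_penalty
    )
    # move candidates into face-local coordinates for the pairing geometry
    ox, oy = region.box.x - face.x, region.box.y - face.y
    face_cands = [replace(c, x=c.x + ox, y=c.y + oy) for c in scored]
    left, right = iris.select_pair(face_cands, face.w, cfg.ipd_mean, cfg.ipd_sigma)
    t = _stage(log, "candidates", t, n_candidates=len(scored))

    face_gray = face.crop(gray)
    estimates = {}
    for side, est in (("left", left), ("right", right)):
        cx, cy = iris.refine_center(face_gray, (est.x, est.y), rr.r_min, cfg.blur_sigma)
        # radius from a local ROI around the refined centre
        m = 2 * rr.r_max
        x0, y0 = max(cx - m, 0), max(cy - m, 0)
        roi = face_gray[y0 : cy + m + 1, x0 : cx + m + 1]
        proj = iris.radial_projection(
            roi, (cx - x0, cy - y0), rr,
            k=cfg.gradient_floor_percent, theta_deg=cfg.theta_deg,
            blur_sigma=cfg.blur_sigma,
        )
        radius = iris.select_radius(proj, rr)
        estimates[side] = iris.IrisEstimate(cx, cy, radius, est.confidence)
    t = _stage(
        log, "centers_radii", t,
        left=[estimates["left"].x, estimates["left"].y, estimates["left"].radius],
        right=[estimates["right"].x, estimates["right"].y, estimates["right"].radius],
    )

    prob = None
    if lut is not None and cfg.fit_shape:
        prob = probability_map(face.crop(np.asarray(img)), lut)
        t = _stage(log, "probability_map", t)

    doc = AnnotationDoc(meta={"face": [face.x, face.y, face.w, face.h]})
    for side, est in estimates.items():
        ann = EyeAnnotation(
            pupil_center=(est.x + face.x, est.y + face.y),
            iris_radius=float(est.radius),
            confidence=float(est.confidence),
        )
        if prob is not None:
            rng = np.random.default_rng(cfg.seed + (0 if side == "left" else 1))
            match = replace(cfg.match, seed=cfg.seed)
            shape, corners, _mask = segment_eye(
                prob, (est.x, est.y), est.radius, match, rng=rng
            )
            shape = shape.translated(face.x, face.y)
            (lx, ly), (rx, ry) = corners
            lcorner = (lx + face.x, ly + face.y)
            rcorner = (rx + face.x, ry + face.y)
            if side == "left":  # image-left eye: nose is to its right
                ann.inner_corner, ann.outer_corner = rcorner, lcorner
            else:
                ann.inner_corner, ann.outer_corner = lcorner, rcorner
            ann.top_eyelid_mid = (shape.cx + shape.tx, shape.cy + shape.ty)
            ann.bottom_eyelid_mid = (shape.cx + shape.bx, shape.cy + shape.by)
            ann.shape = [float(v) for v in shape.as_vector()]
        doc.eyes[side] = ann
    if prob is not None:
        t = _stage(log, "eyelid_shape", t)
    return doc, log
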