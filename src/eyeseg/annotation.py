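"""Per-eye annotation records and their JSON/CSV serialisation.

An annotation mirrors the six-landmark scheme used to mark eyes by hand:
pupil centre, the two eye corners, the top and bottom eyelid mid-points and
the iris radius (equivalently a point on the iris boundary).  A document
bundles the two eyes of one image plus a schema version so readers can
refuse formats they do not understand.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict

SCHEMA_VERSION = 1

_REQUIRED_EYE_FIELDS = ("pupil_center",)


@dataclass
class EyeAnnotation:
    """Ground truth or prediction for a single eye.

    Coordinates are 0-based floats at pixel centres, in full-image
    coordinates.  Optional fields are ``None`` when a stage did not run
    (e.g. shape fitting disabled).
    """

    pupil_center: tuple[float, float]
    iris_radius: float | None = None
    inner_corner: tuple[float, float] | None = None
    outer_corner: tuple[float, float] | None = None
    top_eyelid_mid: tuple[float, float] | None = None
    bottom_eyelid_mid: tuple[float, float] | None = None
    shape: list[float] | None = None  # 12-value eyelid control vector
    confidence: float | None = None


@dataclass
class AnnotationDoc:
    eyes: dict[str, EyeAnnotation] = field(default_factory=dict)  # "left"/"right"
    image: str | None = None
    schema_version: int = SCHEMA_VERSION
    meta: dict = field(default_factory=dict)


def _round_floats(obj, nd=4):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    return obj


def to_dict(doc: AnnotationDoc) -> dict:
    return _round_floats(
        {
            "schema_version": doc.schema_version,
            "image": doc.image,
            "eyes": {side: asdict(eye) for side, eye in doc.eyes.items()},
            "meta": doc.meta,
        }
    )


def write_annotation(path, doc: AnnotationDoc) -> None:
    with open(path, "w") as fh:
        json.dump(to_dict(doc), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _parse_eye(d: dict) -> EyeAnnotation:
    for name in _REQUIRED_EYE_FIELDS:
        if d.get(name) is None:
            raise ValueError(f"annotation missing required field {name!r}")
    known = {f for f in EyeAnnotation.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown annotation fields: {sorted(unknown)}")
    kw = dict(d)
    kw["pupil_center"] = tuple(kw["pupil_center"])
    for name in ("inner_corner", "outer_corner", "top_eyelid_mid", "bottom_eyelid_mid"):
        if kw.get(name) is not None:
            kw[name] = tuple(kw[name])
    return EyeAnnotation(**kw)


def read_annotation(path) -> AnnotationDoc:
    with open(path) as fh:
        raw = json.load(fh)
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported annotation schema version {version!r}")
    eyes = {side: _parse_eye(d) for side, d in raw.get("eyes", {}).items()}
    return AnnotationDoc(
        eyes=eyes,
        image=raw.get("image"),
        schema_version=version,
        meta=raw.get("meta", {}),
    )


def export_csv(path, docs: list[AnnotationDoc]) -> None:
    """One row per eye: image, side, landmarks flattened."""
    cols = [
        "image", "side", "pupil_x", "pupil_y", "iris_radius",
        "inner_x", "inner_y", "outer_x", "outer_y",
        "top_x", "top_y", "bottom_x", "bottom_y", "confidence",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for doc in docs:
            for side, eye in sorted(doc.eyes.items()):
                def xy(p):
                    return ("", "") if p is None else (p[0], p[1])
                row = [doc.image or "", side, *eye.pupil_center,
                       "" if eye.iris_radius is None else eye.iris_radius,
                       *xy(eye.inner_corner), *xy(eye.outer_corner),
                       *xy(eye.top_eyelid_mid), *xy(eye.bottom_eyelid_mid),
                       "" if eye.confidence is None else eye.confidence]
                w.writerow(row)
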