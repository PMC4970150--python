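"""Pipeline configuration: one validated bag of per-stage defaults.

Loadable from YAML; unknown keys are rejected so typos fail loudly instead
of silently falling back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields, is_dataclass

import yaml

from .eyelid import MatchParams

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    # face geometry
    crop_fraction: float = 0.70
    eye_band: tuple[float, float] = (0.20, 0.55)
    projection_smoothing: int = 5
    # radial symmetry transform
    frst_alpha: float = 2.0
    frst_sigma_factor: float = 0.25
    radius_tolerance: float = 0.3
    # candidate scoring / pairing
    blur_sigma: float = 2.0
    eyebrow_penalty: float = 0.5
    ipd_mean: float = 0.4
    ipd_sigma: float = 0.1
    # radius estimation
    gradient_floor_percent: float = 20.0
    theta_deg: tuple[float, float] = (-45.0, 45.0)
    # eyelid shape
    match: MatchParams = field(default_factory=MatchParams)
    fit_shape: bool = True
    include_o3: bool = False
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(_to_plain(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _to_plain(obj):
    if is_dataclass(obj):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _from_mapping(cls, data: dict):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        if name == "match" and isinstance(value, dict):
            value = _from_mapping(MatchParams, value)
        elif f.type.startswith("tuple") and isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a PipelineConfig from YAML, applying optional overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    return _from_mapping(PipelineConfig, data)
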