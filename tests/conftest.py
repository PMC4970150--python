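"""Shared fixtures: rendered scenes, a trained sclera model and its LUT."""

import numpy as np
import pytest

from eyeseg.sclera import build_lut, train_classifier
from eyeseg.synthetic import FaceRenderSpec, render_face, training_pixels


@pytest.fixture(scope="session")
def sclera_model():
    pos, neg = training_pixels(n_images=4, seed=0)
    return train_classifier(pos, neg, seed=0)


@pytest.fixture(scope="session")
def sclera_lut(sclera_model):
    # ~16.7M colour evaluations; built once per session
    return build_lut(sclera_model)


@pytest.fixture(scope="session")
def clean_face():
    """One noise-free-ish face render with exact annotations."""
    return render_face(FaceRenderSpec(seed=0))


def dark_disk(radius: int, center=None, size=None, seed=0, noise=2.0):
    """Dark disk on a bright background with mild pixel noise."""
    rng = np.random.default_rng(seed)
    size = size or (6 * radius + 11, 6 * radius + 11)
    h, w = size
    if center is None:
        cx = int(rng.integers(2 * radius + 2, w - 2 * radius - 2))
        cy = int(rng.integers(2 * radius + 2, h - 2 * radius - 2))
    else:
        cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.where((xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2, 30.0, 220.0)
    img = np.clip(img + rng.normal(0, noise, img.shape), 0, 255)
    return img, (cx, cy)
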