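"""Sclera colour model: features, linear SVM, Platt calibration, 24-bit LUT.

The sclera (the white of the eye) is separated from skin, iris and lash
pixels purely by colour.  Each pixel is described by its HSV hue and the
chromatic channels of the RGB opponent colour space

    O1 = (R - G) / sqrt(2)
    O2 = (R + G - 2B) / sqrt(6)
    O3 = (R + G + B) / sqrt(3)   (intensity; excluded by default)

A linear max-margin classifier is trained on pooled patch pixels and its
decision values are calibrated to probabilities with a Platt sigmoid
``P(sclera | d) = 1 / (1 + exp(A d + B))``.  Because a 24-bit image has a
finite colour set, the calibrated model is compiled once into a 2^24-entry
lookup table so that classifying a pixel is a single array index.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

__all__ = [
    "PlattParams",
    "ScleraModel",
    "ScleraLUT",
    "opponent_transform",
    "extract_features",
    "fit_platt",
    "train_classifier",
    "build_lut",
    "probability_map",
]

_SQRT2, _SQRT6, _SQRT3 = np.sqrt(2.0), np.sqrt(6.0), np.sqrt(3.0)
_LUT_MAGIC = b"SCLERLUT"
_LUT_VERSION = 1
_HEADER_SIZE = 32


def opponent_transform(rgb: np.ndarray) -> np.ndarray:
    """Opponent colour channels (..., 3) for RGB input in [0, 255]."""
    rgb = np.asarray(rgb, dtype=np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    return np.stack(
        [(r - g) / _SQRT2, (r + g - 2.0 * b) / _SQRT6, (r + g + b) / _SQRT3], axis=-1
    )


def extract_features(rgb: np.ndarray, include_o3: bool = False) -> np.ndarray:
    """Colour feature vectors: (hue, O1, O2[, O3]) per pixel.

    Hue is in [0, 1); achromatic pixels get hue 0 by convention.  Input may
    be (N, 3) pixels or an (H, W, 3) image; output matches with a trailing
    feature axis.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    flat = rgb.reshape(-1, 1, 3)
    hue = rgb2hsv(flat / 255.0)[..., 0].reshape(rgb.shape[:-1])
    opp = opponent_transform(rgb)
    cols = [hue, opp[..., 0], opp[..., 1]]
    if include_o3:
        cols.append(opp[..., 2])
    return np.stack(cols, axis=-1)


@dataclass(frozen=True)
class PlattParams:
    A: float
    B: float

    def __call__(self, decision: np.ndarray) -> np.ndarray:
        z = self.A * np.asarray(decision, dtype=np.float64) + self.B
        # numerically stable logistic
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = np.exp(-z[pos]) / (1.0 + np.exp(-z[pos]))
        out[~pos] = 1.0 / (1.0 + np.exp(z[~pos]))
        return out


def fit_platt(decision: np.ndarray, labels: np.ndarray, max_iter: int = 100) -> PlattParams:
    """Platt sigmoid fit by Newton iteration with prior-corrected targets.

    ``labels`` are binary (1 = positive class).  The targets are shrunk to
    (N+ + 1)/(N+ + 2) and 1/(N- + 2) to regularise the maximum-likelihood
    fit, and a backtracking line search keeps the iteration stable.
    """
    d = np.asarray(decision, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Platt fitting needs both classes")
    t = np.where(y, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    A, B = 0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))

    def nll(a, b):
        z = a * d + b
        # log(1 + exp(z)) - t*... stable form of cross-entropy on sigma(-z)
        return float(np.sum(np.logaddexp(0.0, z) - (1.0 - t) * z))

    f = nll(A, B)
    for _ in range(max_iter):
        z = A * d + B
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))  # P(positive | d)
        grad_common = (1.0 - p) - (1.0 - t)  # d nll / dz  (= t - p with sign)
        gA = float(np.sum(grad_common * d))
        gB = float(np.sum(grad_common))
        wgt = p * (1.0 - p)
        hAA = float(np.sum(wgt * d * d)) + 1e-12
        hAB = float(np.sum(wgt * d))
        hBB = float(np.sum(wgt)) + 1e-12
        det = hAA * hBB - hAB * hAB
        if abs(det) < 1e-18:
            break
        dA = -(hBB * gA - hAB * gB) / det
        dB = -(hAA * gB - hAB * gA) / det
        step = 1.0
        while step > 1e-10:
            fa = nll(A + step * dA, B + step * dB)
            if fa < f + 1e-4 * step * (gA * dA + gB * dB):
                break
            step /= 2.0
        A += step * dA
        B += step * dB
        new_f = nll(A, B)
        if abs(f - new_f) < 1e-10:
            f = new_f
            break
        f = new_f
    return PlattParams(A, B)


@dataclass
class ScleraModel:
    """Standardised linear classifier plus Platt calibration."""

    weights: np.ndarray  # on standardised features
    bias: float
    feat_mean: np.ndarray
    feat_std: np.ndarray
    platt: PlattParams
    include_o3: bool = False

    def decision(self, rgb: np.ndarray) -> np.ndarray:
        feats = extract_features(rgb, self.include_o3)
        z = (feats - self.feat_mean) / self.feat_std
        return z @ self.weights + self.bias

    def probability(self, rgb: np.ndarray) -> np.ndarray:
        return self.platt(self.decision(rgb))


def train_classifier(
    pos_pixels: np.ndarray,
    neg_pixels: np.ndarray,
    include_o3: bool = False,
    C: float = 1.0,
    n_folds: int = 5,
    seed: int = 0,
) -> ScleraModel:
    """Train the sclera/non-sclera pixel classifier.

    ``pos_pixels``/``neg_pixels`` are (N, 3) uint8 RGB arrays pooled from
    labelled patches.  Features are standardised by the training mean and
    standard deviation; Platt calibration is fitted on out-of-fold decision
    values so the sigmoid is not tuned on resubstitution scores.
    """
    pos = np.asarray(pos_pixels).reshape(-1, 3)
    neg = np.asarray(neg_pixels).reshape(-1, 3)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both sclera and non-sclera pixels are required")
    X = extract_features(np.vstack([pos, neg]), include_o3)
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std

    svm = LinearSVC(C=C, dual=False)
    svm.fit(Z, y)
    # out-of-fold decision values for calibration
    folds = min(n_folds, int(np.bincount(y.astype(int)).min()))
    if folds >= 2:
        dec = np.empty(len(y))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for tr, te in skf.split(Z, y):
            f = LinearSVC(C=C, dual=False)
            f.fit(Z[tr], y[tr])
            dec[te] = f.decision_function(Z[te])
    else:
        dec = svm.decision_function(Z)
    platt = fit_platt(dec, y)
    return ScleraModel(
        weights=svm.coef_.ravel().copy(),
        bias=float(svm.intercept_[0]),
        feat_mean=mean,
        feat_std=std,
        platt=platt,
        include_o3=include_o3,
    )


class ScleraLUT:
    """Probability-of-sclera per 24-bit RGB colour, 8-bit quantised.

    The table index is ``(R << 16) | (G << 8) | B``; entries are stored as
    uint8 so the whole table is exactly 16 MiB.
    """

    def __init__(self, table: np.ndarray, include_o3: bool = False):
        table = np.asarray(table, dtype=np.uint8)
        if table.shape != (1 << 24,):
            raise ValueError("LUT must have exactly 2^24 entries")
        self.table = table
        self.include_o3 = include_o3

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self, rgb: np.ndarray) -> np.ndarray:
        """Probabilities in [0, 1] for (..., 3) uint8 RGB input."""
        rgb = np.asarray(rgb, dtype=np.uint32)
        idx = (rgb[..., 0] << 16) | (rgb[..., 1] << 8) | rgb[..., 2]
        return self.table[idx] / 255.0

    def save(self, path) -> None:
        header = struct.pack(
            "<8sHHB19x", _LUT_MAGIC, _LUT_VERSION, _HEADER_SIZE, int(self.include_o3)
        )
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(self.table.tobytes())

    @classmethod
    def load(cls, path) -> "ScleraLUT":
        with open(path, "rb") as fh:
            header = fh.read(_HEADER_SIZE)
            magic, version, hsize, o3 = struct.unpack("<8sHHB19x", header)
            if magic != _LUT_MAGIC:
                raise ValueError("not a sclera LUT file")
            if version != _LUT_VERSION:
                raise ValueError(f"unsupported LUT version {version}")
            table = np.frombuffer(fh.read(1 << 24), dtype=np.uint8).copy()
        return cls(table, include_o3=bool(o3))


def build_lut(model: ScleraModel, chunk: int = 1 << 20) -> ScleraLUT:
    """Compile the calibrated model into the full 2^24-colour table."""
    n = 1 << 24
    table = np.empty(n, dtype=np.uint8)
    for start in range(0, n, chunk):
        idx = np.arange(start, min(start + chunk, n), dtype=np.uint32)
        rgb = np.stack(
            [(idx >> 16) & 255, (idx >> 8) & 255, idx & 255], axis=-1
        ).astype(np.uint8)
        p = model.probability(rgb)
        table[start : start + len(idx)] = np.rint(p * 255.0).astype(np.uint8)
    return ScleraLUT(table, include_o3=model.include_o3)


def probability_map(
    img: np.ndarray, lut: ScleraLUT, roi: tuple[int, int, int, int] | None = None
) -> np.ndarray:
    """Per-pixel sclera probability over an (x, y, w, h) ROI (or full image)."""
    img = np.asarray(img)
    if roi is not None:
        x, y, w, h = roi
        img = img[y : y + h, x : x + w]
    return lut.lookup(img)
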