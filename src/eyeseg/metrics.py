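"""Evaluation measures for eye-feature estimates.

Centre errors are Euclidean distances normalised by the true inter-centre
distance (wec/aec/bec: worst/average/best of the two eyes); radius errors
are absolute deviations normalised by the mean true radius (aer/wer/ber);
eye-region masks are compared by pixel confusion counts and the usual
sensitivity/specificity/accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EyePairTruth",
    "EyePairEstimate",
    "ConfusionCounts",
    "center_errors",
    "radius_errors",
    "pixel_confusion",
    "classification_measures",
    "accuracy_curve",
]


@dataclass(frozen=True)
class EyePairTruth:
    cl: tuple[float, float]
    cr: tuple[float, float]
    rl: float
    rr: float


@dataclass(frozen=True)
class EyePairEstimate:
    cl: tuple[float, float]
    cr: tuple[float, float]
    rl: float | None = None
    rr: float | None = None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _dist(a, b) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def center_errors(truth: EyePairTruth, est: EyePairEstimate) -> tuple[float, float, float]:
    """(wec, aec, bec): worst/average/best normalised eye-centre error.

    Normalisation is by the true inter-centre distance, so wec <= 0.25
    roughly means "within the eye", <= 0.10 within the iris and <= 0.05
    within the pupil.
    """
    ipd = _dist(truth.cl, truth.cr)
    if ipd == 0:
        raise ValueError("true eye centres coincide; error undefined")
    el = _dist(truth.cl, est.cl)
    er = _dist(truth.cr, est.cr)
    return max(el, er) / ipd, (el + er) / 2.0 / ipd, min(el, er) / ipd


def radius_errors(truth: EyePairTruth, est: EyePairEstimate) -> tuple[float, float, float]:
    """(aer, wer, ber): normalised iris-radius errors.

    All three are normalised by the mean true radius (rl + rr) / 2, so the
    identity aer = (wer + ber) / 2 holds exactly.
    """
    if truth.rl + truth.rr <= 0 or truth.rl <= 0 or truth.rr <= 0:
        raise ValueError("true radii must be positive")
    if est.rl is None or est.rr is None:
        raise ValueError("estimate lacks radii")
    dl = abs(est.rl - truth.rl)
    dr = abs(est.rr - truth.rr)
    denom = truth.rl + truth.rr
    return (dl + dr) / denom, 2.0 * max(dl, dr) / denom, 2.0 * min(dl, dr) / denom


def pixel_confusion(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    """Pixel counts with "positive" = eye-region pixel."""
    pred = np.asarray(pred_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def classification_measures(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from confusion counts."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0 or c.total == 0:
        raise ValueError("a confusion denominator is zero; measure undefined")
    return (
        c.tp / (c.tp + c.fn),
        c.tn / (c.tn + c.fp),
        (c.tp + c.tn) / c.total,
    )


def accuracy_curve(wec_values, thresholds=None) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of images with wec <= t, for a grid of thresholds t.

    This is the cumulative accuracy-vs-threshold curve commonly reported for
    eye-centre localisation benchmarks.
    """
    wec = np.asarray(wec_values, dtype=np.float64)
    if thresholds is None:
        thresholds = np.linspace(0.0, 0.25, 51)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    frac = np.array([(wec <= t).mean() for t in thresholds])
    return thresholds, frac
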