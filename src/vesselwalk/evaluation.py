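"""Pixelwise evaluation of a segmentation against ground truth.

All counting is restricted to the field of view: pixels outside the
camera aperture carry no retinal content and are excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class MetricReport:
    """Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/(TP+FN+TN+FP)."""

    sensitivity: float
    specificity: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def confusion(
    pred: np.ndarray, truth: np.ndarray, fov: np.ndarray
) -> ConfusionCounts:
    """Confusion counts over in-FOV pixels only."""
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    fov = np.asarray(fov, bool)
    if not (pred.shape == truth.shape == fov.shape):
        raise ValueError(
            f"shape mismatch: pred {pred.shape}, truth {truth.shape}, "
            f"fov {fov.shape}")
    p = pred[fov]
    t = truth[fov]
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def metrics(c: ConfusionCounts) -> MetricReport:
    """Sensitivity, specificity and accuracy from confusion counts."""
    if c.tp + c.fn == 0:
        raise ValueError("no positive pixels in truth: sensitivity undefined")
    if c.tn + c.fp == 0:
        raise ValueError("no negative pixels in truth: specificity undefined")
    total = c.tp + c.fn + c.tn + c.fp
    return MetricReport(
        sensitivity=c.tp / (c.tp + c.fn),
        specificity=c.tn / (c.tn + c.fp),
        accuracy=(c.tp + c.tn) / total,
    )


def dice(pred: np.ndarray, truth: np.ndarray,
         fov: np.ndarray | None = None) -> float:
    """Dice overlap 2|A&B| / (|A|+|B|), optionally restricted to the FOV."""
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    if fov is not None:
        fov = np.asarray(fov, bool)
        pred = pred & fov
        truth = truth & fov
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pred & truth).sum()) / denom


def mean_metrics(reports: list[MetricReport]) -> MetricReport:
    """Arithmetic per-image mean of a batch of metric reports."""
    if not reports:
        raise ValueError("empty report list")
    return MetricReport(
        sensitivity=float(np.mean([r.sensitivity for r in reports])),
        specificity=float(np.mean([r.specificity for r in reports])),
        accuracy=float(np.mean([r.accuracy for r in reports])),
    )
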