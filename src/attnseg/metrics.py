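"""Segmentation evaluation: Dice similarity and confusion-matrix metrics.

Regions are the standard nested tumor composites built from voxel labels:
WT (whole tumor) = {1,2,3}, TC (tumor core) = {1,3}, ET (enhancing) = {3}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

REGIONS = ("ET", "WT", "TC")

#: label sets defining each composite region
REGION_LABELS = {"WT": (1, 2, 3), "TC": (1, 3), "ET": (3,)}


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts for one binary comparison."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Per-region Dice plus binary confusion metrics (None where undefined)."""

    dsc: dict[str, float] = field(default_factory=dict)
    sensitivity: dict[str, Optional[float]] = field(default_factory=dict)
    specificity: dict[str, Optional[float]] = field(default_factory=dict)
    precision: dict[str, Optional[float]] = field(default_factory=dict)
    accuracy: dict[str, Optional[float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "dsc": dict(self.dsc),
            "sensitivity": dict(self.sensitivity),
            "specificity": dict(self.specificity),
            "precision": dict(self.precision),
            "accuracy": dict(self.accuracy),
        }


def region_masks(labels: np.ndarray) -> dict[str, np.ndarray]:
    """Binary masks of the nested composites ET = {3} subset of TC = {1,3} subset of WT = {1,2,3}."""
    labels = np.asarray(labels)
    bad = np.setdiff1d(np.unique(labels), [0, 1, 2, 3])
    if bad.size:
        raise ValueError(f"label values outside {{0,1,2,3}}: {bad.tolist()}")
    return {
        region: np.isin(labels, REGION_LABELS[region])
        for region in REGIONS
    }


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A.B| / (|A| + |B|).

    Both-empty masks score 1.0 (perfect-agreement convention); an empty
    mask against a nonempty one scores 0.0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def confusion_metrics(
    pred: np.ndarray, truth: np.ndarray
) -> tuple[ConfusionCounts, Optional[float], Optional[float], Optional[float], Optional[float]]:
    """Confusion counts plus (sensitivity, specificity, precision, accuracy).

    Ratios with zero denominators are returned as None, not 0.
    """
    c = confusion_counts(pred, truth)
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    precision = _ratio(c.tp, c.tp + c.fp)
    accuracy = _ratio(c.tp + c.tn, c.total)
    return c, sensitivity, specificity, precision, accuracy


def dsc_from_counts(c: ConfusionCounts) -> float:
    """Dice from confusion counts: 2TP / (2TP + FN + FP); both-empty -> 1."""
    denom = 2 * c.tp + c.fn + c.fp
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def evaluate_masks(pred_labels: np.ndarray, truth_labels: np.ndarray) -> MetricsReport:
    """Full per-region report comparing two label volumes."""
    pred_regions = region_masks(pred_labels)
    truth_regions = region_masks(truth_labels)
    report = MetricsReport()
    for region in REGIONS:
        p, t = pred_regions[region], truth_regions[region]
        report.dsc[region] = dsc(p, t)
        _, sens, spec, prec, acc = confusion_metrics(p, t)
        report.sensitivity[region] = sens
        report.specificity[region] = spec
        report.precision[region] = prec
        report.accuracy[region] = acc
    return report
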