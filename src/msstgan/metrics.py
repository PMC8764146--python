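"""Segmentation evaluation: Dice, sensitivity, Jaccard, Pearson correlation.

Metrics are computed per image from pixel confusion counts and aggregated
as mean +/- population standard deviation. When both prediction and ground
truth are empty the overlap metrics are defined as 1.0 (perfect agreement);
Pearson correlation is undefined for constant inputs and such images are
excluded from its aggregate with a logged warning.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts", "MetricReport", "binarize", "confusion",
    "dsc", "sen", "jac", "ppmcc", "evaluate_set",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def binarize(pred: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; pixel = 1 iff probability >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return (np.asarray(pred, dtype=float) >= threshold).astype(np.uint8)


def confusion(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Pixel confusion tallies between two binary masks of equal shape."""
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(f"mask shapes differ: {pred_mask.shape} vs {gt_mask.shape}")
    for name, m in (("prediction", pred_mask), ("ground truth", gt_mask)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    p = pred_mask.astype(bool)
    g = gt_mask.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & g)), fp=int(np.sum(p & ~g)),
        tn=int(np.sum(~p & ~g)), fn=int(np.sum(~p & g)))


def _safe_ratio(num: float, den: float) -> float:
    if den == 0:
        # empty prediction and empty ground truth: perfect agreement
        log.info("empty prediction and ground truth; metric defined as 1.0")
        return 1.0
    return num / den


def dsc(c: ConfusionCounts) -> float:
    """Dice coefficient 2TP / (2TP + FP + FN)."""
    return _safe_ratio(2.0 * c.tp, 2.0 * c.tp + c.fp + c.fn)


def sen(c: ConfusionCounts) -> float:
    """Sensitivity (recall) TP / (TP + FN)."""
    return _safe_ratio(float(c.tp), float(c.tp + c.fn))


def jac(c: ConfusionCounts) -> float:
    """Jaccard index TP / (TP + FP + FN)."""
    return _safe_ratio(float(c.tp), float(c.tp + c.fp + c.fn))


def ppmcc(pred: np.ndarray, gt: np.ndarray) -> float:
    """Pearson product-moment correlation over flattened pixels.

    Returns NaN (flagged missing, excluded from aggregation) when either
    input has zero variance.
    """
    x = np.asarray(pred, dtype=float).ravel()
    y = np.asarray(gt, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"flattened sizes differ: {x.shape} vs {y.shape}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant input to Pearson correlation; value undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class MetricReport:
    """Per-image metric values plus mean +/- population std per metric."""

    per_image: dict[str, list[float]] = field(default_factory=dict)

    METRICS = ("dsc", "sen", "jac", "ppmcc")

    def mean(self, metric: str) -> float:
        vals = [v for v in self.per_image[metric] if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def std(self, metric: str) -> float:
        vals = [v for v in self.per_image[metric] if not math.isnan(v)]
        return float(np.std(vals)) if vals else float("nan")

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.std(m)) for m in self.METRICS}

    def to_json(self, path) -> None:
        payload = {
            "per_image": self.per_image,
            "summary": {m: {"mean": self.mean(m), "std": self.std(m)}
                        for m in self.METRICS},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path) -> None:
        n = len(self.per_image["dsc"])
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image", *self.METRICS])
            for i in range(n):
                writer.writerow([i, *(f"{self.per_image[m][i]:.6f}" for m in self.METRICS)])
            writer.writerow(["mean", *(f"{self.mean(m):.6f}" for m in self.METRICS)])
            writer.writerow(["std", *(f"{self.std(m):.6f}" for m in self.METRICS)])


def evaluate_set(preds, gts, threshold: float = 0.5) -> MetricReport:
    """Per-image metrics over paired prediction/ground-truth lists.

    Predictions may be soft probability maps (binarized at ``threshold``
    for the overlap metrics; Pearson correlation uses the soft values).
    """
    preds, gts = list(preds), list(gts)
    if not preds:
        raise ValueError("empty evaluation set")
    if len(preds) != len(gts):
        raise ValueError(f"{len(preds)} predictions vs {len(gts)} ground truths")
    report = MetricReport(per_image={m: [] for m in MetricReport.METRICS})
    for pred, gt in zip(preds, gts):
        pm = binarize(pred, threshold)
        c = confusion(pm, np.asarray(gt).astype(np.uint8))
        d, j = dsc(c), jac(c)
        # algebraic identity between Dice and Jaccard, asserted on every pair
        assert abs(d - 2.0 * j / (1.0 + j)) < 1e-12
        report.per_image["dsc"].append(d)
        report.per_image["sen"].append(sen(c))
        report.per_image["jac"].append(j)
        report.per_image["ppmcc"].append(ppmcc(pred, gt))
    return report
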