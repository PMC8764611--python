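"""Joint segmentation/detection scoring and volume quantification.

Per-image IoU uses the fluid-free conventions: an image with an empty
ground-truth mask scores 1 if the prediction is also empty and 0 if
anything was (spuriously) segmented; otherwise IoU is |intersection| /
|union|.  Slice-level detection scores each slice by its predicted-
positive pixel fraction (at inference no ground truth is available, so
a truth-dependent rule cannot apply); sweeping the declaration
threshold yields the ROC curve, and AUROC is the trapezoidal area,
identical to the pair-concordance statistic with ties half-credited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import validate_binary_mask


@dataclass(frozen=True)
class IoUScore:
    value: float
    case: str  # standard | empty_empty | spurious_on_normal


def binarize(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Pixel = 1 iff probability >= threshold (inclusive)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(probabilities) >= threshold).astype(np.uint8)


def iou(pred: np.ndarray, truth: np.ndarray) -> IoUScore:
    """Per-image IoU with the 0/1 conventions for fluid-free images."""
    pred = validate_binary_mask(pred)
    truth = validate_binary_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"prediction {pred.shape} and truth {truth.shape} grids differ")
    t = bool(truth.any())
    p = bool(pred.any())
    if not t:
        if not p:
            return IoUScore(1.0, "empty_empty")
        return IoUScore(0.0, "spurious_on_normal")
    inter = int(np.logical_and(pred, truth).sum())
    union = int(np.logical_or(pred, truth).sum())
    return IoUScore(inter / union, "standard")


def mean_iou(scores: list[IoUScore | float]) -> float:
    if len(scores) == 0:
        raise ValueError("mean IoU of an empty list is undefined")
    return float(np.mean([s.value if isinstance(s, IoUScore) else float(s) for s in scores]))


def detection_score(pred: np.ndarray) -> float:
    """Predicted-positive pixel fraction of a mask, in [0, 1]."""
    pred = validate_binary_mask(pred)
    return float(pred.sum() / pred.size)


def truth_iou_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Truth-dependent per-image IoU used as a declaration statistic.

    Only applicable where ground truth exists (validation analysis);
    inference-time detection uses :func:`detection_score`.
    """
    return iou(pred, truth).value


def classify_slices(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Declare ascites iff score >= threshold (inclusive); 1 = ascites."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC over declaration thresholds; AUROC by trapezoidal integration."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present in labels")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auroc=float(_sk_auc(fpr, tpr)))


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(truth: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    t = np.asarray(truth).astype(bool)
    p = np.asarray(predictions).astype(bool)
    if t.shape != p.shape:
        raise ValueError("truth and prediction sequences differ in length")
    return ConfusionCounts(
        TP=int(np.sum(t & p)),
        FP=int(np.sum(~t & p)),
        TN=int(np.sum(~t & ~p)),
        FN=int(np.sum(t & ~p)),
    )


@dataclass(frozen=True)
class DetectionMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    precision: float
    f1: float


def detection_metrics(counts: ConfusionCounts) -> DetectionMetrics:
    """Sensitivity, specificity, accuracy, balanced accuracy, precision, F1.

    Undefined denominators raise (a silent zero would corrupt averaged
    reports).
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    if tp + fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive ground truth (TP+FN=0)")
    if tn + fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative ground truth (TN+FP=0)")
    if tp + fp == 0:
        raise ZeroDivisionError("precision undefined: no positive predictions (TP+FP=0)")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / counts.total
    prec = tp / (tp + fp)
    bal, f1 = metrics_from_rates(sens, spec, prec)
    return DetectionMetrics(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        balanced_accuracy=bal,
        precision=prec,
        f1=f1,
    )


def metrics_from_rates(
    sensitivity: float, specificity: float, precision: float
) -> tuple[float, float]:
    """(balanced accuracy, F1) from the three printed rates.

    balanced accuracy = (sensitivity + specificity) / 2;
    F1 = 2 * sensitivity * precision / (sensitivity + precision).
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("precision", precision)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    bal = (sensitivity + specificity) / 2.0
    if sensitivity + precision == 0:
        raise ZeroDivisionError("F1 undefined: sensitivity + precision = 0")
    f1 = 2.0 * sensitivity * precision / (sensitivity + precision)
    return bal, f1


def round_half_up(x: float, decimals: int = 2) -> float:
    """Half-up decimal rounding used for tabulated comparisons."""
    factor = 10.0**decimals
    return float(np.floor(x * factor + 0.5) / factor)


@dataclass(frozen=True)
class VolumeEstimate:
    volume_ml: float
    per_slice_areas_mm2: tuple[float, ...]


def estimate_volume(
    masks: list[np.ndarray] | np.ndarray,
    pixel_spacing_mm: tuple[float, float] | float,
    slice_thickness_mm: float,
) -> VolumeEstimate:
    """Fluid volume: sum over slices of mask area x slice thickness.

    ``pixel_spacing_mm`` must be the spacing of the mask grid actually
    passed in — rescale it when masks were down-sampled (x2 per axis for
    512 -> 256).
    """
    if isinstance(pixel_spacing_mm, (int, float)):
        pixel_spacing_mm = (float(pixel_spacing_mm),) * 2
    if min(pixel_spacing_mm) <= 0 or slice_thickness_mm <= 0:
        raise ValueError("spacing and thickness must be positive")
    px_area = pixel_spacing_mm[0] * pixel_spacing_mm[1]
    areas = tuple(float(validate_binary_mask(m).sum() * px_area) for m in masks)
    return VolumeEstimate(
        volume_ml=float(sum(areas) * slice_thickness_mm / 1000.0),
        per_slice_areas_mm2=areas,
    )


# ---------------------------------------------------------------------------
# full report


@dataclass
class EvaluationReport:
    per_slice: pd.DataFrame
    miou: float
    roc: ROCCurve
    confusion_counts: ConfusionCounts
    metrics: DetectionMetrics | None
    detection_threshold: float
    volumes_ml: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "miou": self.miou,
            "auroc": self.roc.auroc,
            "roc": {
                "thresholds": self.roc.thresholds.tolist(),
                "fpr": self.roc.fpr.tolist(),
                "tpr": self.roc.tpr.tolist(),
            },
            "detection_threshold": self.detection_threshold,
            "confusion": {
                "TP": self.confusion_counts.TP,
                "FP": self.confusion_counts.FP,
                "TN": self.confusion_counts.TN,
                "FN": self.confusion_counts.FN,
            },
            "metrics": None
            if self.metrics is None
            else {
                "sensitivity": self.metrics.sensitivity,
                "specificity": self.metrics.specificity,
                "accuracy": self.metrics.accuracy,
                "balanced_accuracy": self.metrics.balanced_accuracy,
                "precision": self.metrics.precision,
                "f1": self.metrics.f1,
            },
            "volumes_ml": self.volumes_ml,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(self.to_json_dict(), indent=2))
        self.per_slice.to_csv(outdir / "per_slice.csv", index=False)


def evaluate_predictions(
    pred_masks: list[np.ndarray],
    truth_masks: list[np.ndarray],
    labels: np.ndarray,
    subject_ids: list[str] | None = None,
    pixel_spacing_mm: tuple[float, float] | float = (0.74, 0.74),
    slice_thickness_mm: float = 5.0,
    detection_threshold: float = 0.001,
) -> EvaluationReport:
    """Score a set of predicted masks against ground truth.

    ``detection_threshold`` applies to the predicted-positive area
    fraction (default: declare ascites above 0.1% of pixels).
    """
    scores = np.array([detection_score(p) for p in pred_masks])
    ious = [iou(p, t) for p, t in zip(pred_masks, truth_masks)]
    labels = np.asarray(labels).astype(int)
    rows = pd.DataFrame(
        {
            "subject_id": subject_ids if subject_ids is not None else [""] * len(scores),
            "iou": [s.value for s in ious],
            "iou_case": [s.case for s in ious],
            "detection_score": scores,
            "label": labels,
        }
    )
    roc = roc_curve(scores, labels)
    declared = classify_slices(scores, detection_threshold)
    counts = confusion(labels, declared)
    try:
        metrics = detection_metrics(counts)
    except ZeroDivisionError:
        # e.g. no positive declarations at this threshold: the strict
        # per-metric contract raises, but the report stays usable
        metrics = None
    volumes: dict[str, float] = {}
    if subject_ids is not None:
        for sid in sorted(set(subject_ids)):
            masks = [m for m, s in zip(pred_masks, subject_ids) if s == sid]
            volumes[sid] = estimate_volume(
                masks, pixel_spacing_mm, slice_thickness_mm
            ).volume_ml
    return EvaluationReport(
        per_slice=rows,
        miou=mean_iou(ious),
        roc=roc,
        confusion_counts=counts,
        metrics=metrics,
        detection_threshold=detection_threshold,
        volumes_ml=volumes,
    )
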