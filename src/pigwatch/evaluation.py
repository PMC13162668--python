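"""Detector and duration evaluation.

Detection scoring follows the standard object-detection protocol: predictions
are matched to ground truth greedily in descending confidence, a prediction
being a true positive iff it shares the class of an as-yet unmatched truth
box with IoU at or above the threshold.  From the matched counts,

    P  = TP / (TP + FP)        R  = TP / (TP + FN)
    AP = area under the interpolated precision–recall curve
    mAP = (1/n) Σ_i AP_i       (unweighted over classes)

with mAP50 at IoU 0.5 and mAP50-95 the mean of AP over IoU 0.50:0.05:0.95.
Duration agreement between observed and estimated activity times uses

    MAE  = mean |y − ŷ|
    RMSE = sqrt(mean (y − ŷ)²)
    R²   = 1 − SS_res / SS_tot
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .detections import Detection, FrameDetections, VideoMeta, iou

__all__ = [
    "IOU_50_95",
    "MatchResult",
    "ScoredPrediction",
    "EvaluationReport",
    "DurationMetrics",
    "match_detections",
    "precision",
    "recall",
    "average_precision",
    "mean_ap",
    "evaluate_detections",
    "duration_metrics",
]

#: the ten IoU thresholds behind mAP50-95
IOU_50_95: tuple[float, ...] = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


@dataclass(frozen=True)
class ScoredPrediction:
    """One prediction's contribution to the PR curve of its class."""

    confidence: float
    is_tp: bool


@dataclass
class MatchResult:
    """Per-class TP/FP/FN counts plus the matched pairs with their IoU."""

    tp: dict[str, int]
    fp: dict[str, int]
    fn: dict[str, int]
    matches: list[tuple[int, int, float]]  # (prediction idx, truth idx, IoU)
    scored: dict[str, list[ScoredPrediction]]
    n_truth: dict[str, int]

    def merge(self, other: "MatchResult") -> "MatchResult":
        """Accumulate another frame's result (pair indices are dropped)."""
        classes = set(self.n_truth) | set(other.n_truth)
        return MatchResult(
            tp={c: self.tp.get(c, 0) + other.tp.get(c, 0) for c in classes},
            fp={c: self.fp.get(c, 0) + other.fp.get(c, 0) for c in classes},
            fn={c: self.fn.get(c, 0) + other.fn.get(c, 0) for c in classes},
            matches=[],
            scored={
                c: self.scored.get(c, []) + other.scored.get(c, []) for c in classes
            },
            n_truth={
                c: self.n_truth.get(c, 0) + other.n_truth.get(c, 0) for c in classes
            },
        )


def match_detections(
    predictions: Sequence[Detection],
    truths: Sequence[Detection],
    meta: VideoMeta,
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedily match one frame's predictions against its ground truth.

    Predictions are visited in descending confidence (missing confidence
    counts as 1.0); each claims the highest-IoU unmatched truth of its class
    with IoU >= threshold.  Unmatched predictions are FP, unmatched truths FN.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError(f"IoU threshold {iou_threshold} outside (0, 1]")
    classes = {d.class_label for d in predictions} | {d.class_label for d in truths}
    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    n_truth = {c: 0 for c in classes}
    for t in truths:
        n_truth[t.class_label] += 1
    scored: dict[str, list[ScoredPrediction]] = {c: [] for c in classes}
    matches: list[tuple[int, int, float]] = []

    truth_px = [t.box.to_pixels(meta) for t in truths]
    pred_px = [p.box.to_pixels(meta) for p in predictions]
    order = sorted(
        range(len(predictions)),
        key=lambda i: -(predictions[i].confidence if predictions[i].confidence is not None else 1.0),
    )
    taken: set[int] = set()
    for i in order:
        pred = predictions[i]
        best_j, best_iou = -1, 0.0
        for j, truth in enumerate(truths):
            if j in taken or truth.class_label != pred.class_label:
                continue
            val = iou(pred_px[i], truth_px[j])
            if val > best_iou:
                best_j, best_iou = j, val
        conf = pred.confidence if pred.confidence is not None else 1.0
        if best_j >= 0 and best_iou >= iou_threshold:
            taken.add(best_j)
            tp[pred.class_label] += 1
            matches.append((i, best_j, best_iou))
            scored[pred.class_label].append(ScoredPrediction(conf, True))
        else:
            fp[pred.class_label] += 1
            scored[pred.class_label].append(ScoredPrediction(conf, False))
    fn = {c: n_truth[c] - tp[c] for c in classes}
    return MatchResult(tp=tp, fp=fp, fn=fn, matches=matches, scored=scored, n_truth=n_truth)


def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP); the degenerate 0/0 case is reported as 0."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be nonnegative")
    return tp / (tp + fp) if tp + fp else 0.0


def recall(tp: int, fn: int) -> float:
    """TP / (TP + FN); the degenerate 0/0 case is reported as 0."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be nonnegative")
    return tp / (tp + fn) if tp + fn else 0.0


def average_precision(
    scored: Sequence[ScoredPrediction],
    n_truth: int,
    method: Literal["continuous", "interp101"] = "continuous",
) -> float:
    """Average precision of one class from its scored predictions.

    ``continuous`` (default) integrates the precision envelope over all
    recall change points; ``interp101`` samples the envelope at 101 evenly
    spaced recall levels.  Raises if the class has no ground truth (AP is
    undefined there).
    """
    if n_truth <= 0:
        raise ValueError("AP undefined for a class with no ground truth")
    if not scored:
        return 0.0
    order = sorted(range(len(scored)), key=lambda i: -scored[i].confidence)
    tps = np.array([scored[i].is_tp for i in order], dtype=float)
    cum_tp = np.cumsum(tps)
    cum_fp = np.cumsum(1.0 - tps)
    rec = cum_tp / n_truth
    prec = cum_tp / (cum_tp + cum_fp)

    mrec = np.concatenate(([0.0], rec, [1.0]))
    mpre = np.concatenate(([1.0], prec, [0.0]))
    mpre = np.flip(np.maximum.accumulate(np.flip(mpre)))  # precision envelope
    if method == "interp101":
        x = np.linspace(0.0, 1.0, 101)
        return float(np.trapezoid(np.interp(x, mrec, mpre), x))
    changes = np.flatnonzero(mrec[1:] != mrec[:-1])
    return float(np.sum((mrec[changes + 1] - mrec[changes]) * mpre[changes + 1]))


def mean_ap(per_class_ap: Mapping[str, float] | Sequence[float]) -> float:
    """Unweighted mean of per-class average precisions."""
    values = list(per_class_ap.values()) if isinstance(per_class_ap, Mapping) else list(per_class_ap)
    if not values:
        raise ValueError("mAP needs at least one class AP")
    return float(np.mean(values))


@dataclass
class EvaluationReport:
    """Per-class and averaged detection metrics, plus optional duration
    agreement metrics."""

    per_class: pd.DataFrame  # columns: class, P, R, AP50, AP50_95
    precision_mean: float
    recall_mean: float
    map50: float
    map50_95: float
    duration: "DurationMetrics | None" = None
    warnings: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Per-class rows plus an 'Average' row, Table-style."""
        avg = pd.DataFrame(
            [
                {
                    "class": "Average",
                    "P": self.precision_mean,
                    "R": self.recall_mean,
                    "AP50": self.map50,
                    "AP50_95": self.map50_95,
                }
            ]
        )
        return pd.concat([self.per_class, avg], ignore_index=True)


def evaluate_detections(
    predictions: Sequence[FrameDetections],
    truths: Sequence[FrameDetections],
    meta: VideoMeta,
    iou_thresholds: Sequence[float] = IOU_50_95,
    ap_method: Literal["continuous", "interp101"] = "continuous",
) -> EvaluationReport:
    """Score a prediction stream against aligned ground-truth frames.

    Frames are paired by frame_index; P/R and the per-class APs use IoU 0.5,
    AP50-95 averages AP over ``iou_thresholds``.  The reported "Average" rows
    are unweighted class means.  Classes with no ground truth anywhere are
    excluded from AP with a warning.
    """
    truth_by_idx = {f.frame_index: f for f in truths}
    pred_by_idx = {f.frame_index: f for f in predictions}
    if len(truth_by_idx) != len(truths) or len(pred_by_idx) != len(predictions):
        raise ValueError("duplicated frame_index in evaluation input")
    indices = sorted(set(truth_by_idx) | set(pred_by_idx))
    empty = FrameDetections(0, 0.0, ())

    per_thr: dict[float, MatchResult] = {}
    for thr in iou_thresholds:
        acc: MatchResult | None = None
        for idx in indices:
            res = match_detections(
                pred_by_idx.get(idx, empty).detections,
                truth_by_idx.get(idx, empty).detections,
                meta,
                iou_threshold=thr,
            )
            acc = res if acc is None else acc.merge(res)
        per_thr[thr] = acc if acc is not None else MatchResult({}, {}, {}, [], {}, {})

    base_thr = 0.5 if 0.5 in per_thr else iou_thresholds[0]
    base = per_thr[base_thr]
    warnings_: list[str] = []
    classes = sorted(c for c in base.n_truth)
    rows = []
    ap_by_class: dict[str, float] = {}
    ap5095_by_class: dict[str, float] = {}
    for c in classes:
        if base.n_truth.get(c, 0) == 0:
            warnings_.append(f"class {c!r} has no ground truth; AP excluded")
            continue
        p = precision(base.tp.get(c, 0), base.fp.get(c, 0))
        r = recall(base.tp.get(c, 0), base.fn.get(c, 0))
        if base.tp.get(c, 0) + base.fp.get(c, 0) == 0:
            warnings_.append(f"class {c!r}: no predictions (degenerate precision)")
        ap50 = average_precision(base.scored.get(c, []), base.n_truth[c], ap_method)
        aps = [
            average_precision(per_thr[t].scored.get(c, []), per_thr[t].n_truth[c], ap_method)
            for t in iou_thresholds
        ]
        ap5095 = float(np.mean(aps))
        ap_by_class[c] = ap50
        ap5095_by_class[c] = ap5095
        rows.append({"class": c, "P": p, "R": r, "AP50": ap50, "AP50_95": ap5095})
    if not rows:
        raise ValueError("no class with ground truth to evaluate")
    per_class = pd.DataFrame(rows)
    return EvaluationReport(
        per_class=per_class,
        precision_mean=float(per_class["P"].mean()),
        recall_mean=float(per_class["R"].mean()),
        map50=mean_ap(ap_by_class),
        map50_95=mean_ap(ap5095_by_class),
        warnings=warnings_,
    )


@dataclass(frozen=True)
class DurationMetrics:
    """Agreement between observed and predicted durations/counts.

    ``r2`` is None when the observed series is constant (SS_tot = 0 makes the
    coefficient of determination undefined); MAE and RMSE are always valid.
    """

    mae: float
    rmse: float
    r2: float | None


def duration_metrics(
    y_true: Sequence[float], y_pred: Sequence[float]
) -> DurationMetrics:
    """MAE, RMSE and R² between equal-length series (length ≥ 2 for R²)."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D series")
    if yt.size == 0:
        raise ValueError("empty series")
    err = yt - yp
    mae = float(np.mean(np.abs(err)))
    rmse = float(math.sqrt(np.mean(err**2)))
    if yt.size < 2:
        return DurationMetrics(mae=mae, rmse=rmse, r2=None)
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0.0:
        return DurationMetrics(mae=mae, rmse=rmse, r2=None)
    ss_res = float(np.sum(err**2))
    return DurationMetrics(mae=mae, rmse=rmse, r2=1.0 - ss_res / ss_tot)
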