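"""Detection evaluation: matching, precision/recall, AP50, mAP50, confusion matrix.

Matching follows the standard greedy protocol: predictions are sorted by
descending confidence (stable; ties broken by prediction index) and each is
assigned to the unmatched same-class ground truth with the highest IoU at or
above the threshold (GT-index ascending on IoU ties).  Average precision is
the exact area under the precision envelope as a function of recall
("all-point" interpolation), evaluated per class and averaged over classes
present in the ground truth for mAP.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import Box, DatasetManifest, read_yolo_labels

logger = logging.getLogger(__name__)

__all__ = [
    "box_iou", "MatchResult", "match_detections", "precision_recall",
    "average_precision", "map50", "confusion_matrix", "PRCurve",
    "EvalReport", "evaluate", "evaluate_dirs", "map50_95", "plot_pr_curves",
]


def box_iou(a: Box, b: Box) -> float:
    """IoU of two normalized center-form boxes (half-open overlap arithmetic)."""
    ax1, ay1, ax2, ay2 = a.to_corners()
    bx1, by1, bx2, by2 = b.to_corners()
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


@dataclass
class MatchResult:
    """Per-prediction TP/FP flags (confidence-annotated) and per-GT hits."""

    tp: np.ndarray          # bool, one per prediction (sorted order)
    conf: np.ndarray        # float, one per prediction (sorted order)
    pred_cls: np.ndarray    # int, one per prediction (sorted order)
    gt_matched: np.ndarray  # bool, one per ground truth
    n_gt: int

    @property
    def n_tp(self) -> int:
        return int(self.tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.tp).sum())

    @property
    def n_fn(self) -> int:
        return self.n_gt - int(self.gt_matched.sum())


def _sorted_pred_order(preds: Sequence[Box]) -> list[int]:
    # stable sort by (-conf, original index)
    return sorted(range(len(preds)), key=lambda i: (-(preds[i].conf or 0.0), i))


def match_detections(preds: Sequence[Box], gts: Sequence[Box],
                     iou_thresh: float = 0.5) -> MatchResult:
    """Greedy confidence-ordered matching of predictions to ground truths.

    Each prediction matches the unmatched same-class GT with the highest IoU
    >= ``iou_thresh`` (lowest GT index on ties); every GT is matched at most
    once.  Empty inputs are allowed.
    """
    order = _sorted_pred_order(preds)
    gt_matched = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(preds), dtype=bool)
    conf = np.array([preds[i].conf or 0.0 for i in order], dtype=float)
    pred_cls = np.array([preds[i].cls for i in order], dtype=int)
    for rank, i in enumerate(order):
        best_iou, best_j = iou_thresh, -1
        for j, gt in enumerate(gts):
            if gt_matched[j] or gt.cls != preds[i].cls:
                continue
            v = box_iou(preds[i], gt)
            if v > best_iou or (v == best_iou and v >= iou_thresh and best_j == -1):
                best_iou, best_j = v, j
        if best_j >= 0:
            gt_matched[best_j] = True
            tp[rank] = True
    return MatchResult(tp, conf, pred_cls, gt_matched, len(gts))


def precision_recall(match: MatchResult) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); empty denominators give P=0, R=1."""
    n_pred = match.n_tp + match.n_fp
    n_gt = match.n_gt
    if n_pred == 0:
        logger.info("no predictions: precision defined as 0")
        p = 0.0
    else:
        p = match.n_tp / n_pred
    if n_gt == 0:
        logger.info("no ground truths: recall defined as 1")
        r = 1.0
    else:
        r = match.n_tp / n_gt
    return p, r


def average_precision(tp: np.ndarray, conf: np.ndarray, n_gt: int) -> float:
    """All-point-interpolated AP from confidence-ranked TP flags.

    The precision curve is made monotone non-increasing from the right
    (envelope) and integrated exactly over recall with rectangles — the exact
    value of the integral of P(R) for a step curve.
    """
    if n_gt == 0:
        return 0.0
    if len(tp) == 0:
        return 0.0
    order = np.lexsort((np.arange(len(conf)), -np.asarray(conf, dtype=float)))
    tp = np.asarray(tp, dtype=bool)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # envelope from the right
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, prec_env):
        if r > r_prev:
            ap += (r - r_prev) * p
            r_prev = r
    return float(ap)


def map50(per_class_ap: Sequence[float]) -> float:
    """Arithmetic mean of per-class AP values."""
    if len(per_class_ap) == 0:
        return 0.0
    return float(np.mean(per_class_ap))


def confusion_matrix(preds: Sequence[Box], gts: Sequence[Box], n_classes: int,
                     iou_thresh: float = 0.45,
                     conf_thresh: float = 0.25) -> np.ndarray:
    """(N+1) x (N+1) detection confusion matrix for one image.

    Rows index predicted class, columns true class, the last row/column being
    background.  Predictions below ``conf_thresh`` are dropped; matching is
    greedy by confidence with cross-class matches allowed, so a wrong-class
    overlap lands off-diagonal.  Unmatched GTs count in the background row;
    unmatched predictions in the background column.
    """
    cm = np.zeros((n_classes + 1, n_classes + 1), dtype=int)
    kept = [p for p in preds if (p.conf or 0.0) >= conf_thresh]
    order = _sorted_pred_order(kept)
    gt_matched = np.zeros(len(gts), dtype=bool)
    for i in order:
        best_iou, best_j = iou_thresh, -1
        for j, gt in enumerate(gts):
            if gt_matched[j]:
                continue
            v = box_iou(kept[i], gt)
            if v > best_iou or (v == best_iou and v >= iou_thresh and best_j == -1):
                best_iou, best_j = v, j
        if best_j >= 0:
            gt_matched[best_j] = True
            cm[kept[i].cls, gts[best_j].cls] += 1
        else:
            cm[kept[i].cls, n_classes] += 1  # pred vs background
    for j, gt in enumerate(gts):
        if not gt_matched[j]:
            cm[n_classes, gt.cls] += 1  # missed GT
    return cm


@dataclass
class PRCurve:
    """Confidence-swept precision-recall points and the resulting AP."""

    recall: np.ndarray
    precision: np.ndarray
    conf: np.ndarray
    ap: float


@dataclass
class EvalReport:
    """Aggregate detection evaluation over a dataset split."""

    class_names: list[str]
    per_class_ap50: dict[str, float]
    map50: float
    precision: float            # at the max-F1 confidence threshold
    recall: float
    f1_conf_threshold: float
    curves: dict[str, PRCurve] = field(repr=False, default_factory=dict)
    confusion: np.ndarray = field(repr=False, default=None)
    classes_absent: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "map50": self.map50,
            "per_class_ap50": self.per_class_ap50,
            "precision": self.precision,
            "recall": self.recall,
            "f1_conf_threshold": self.f1_conf_threshold,
            "classes_absent": self.classes_absent,
            "confusion_matrix": self.confusion.tolist()
            if self.confusion is not None else None,
        }, indent=2)


def _pr_curve(tp: np.ndarray, conf: np.ndarray, n_gt: int) -> PRCurve:
    order = np.lexsort((np.arange(len(conf)), -np.asarray(conf, dtype=float)))
    tp_s = np.asarray(tp, dtype=bool)[order]
    conf_s = np.asarray(conf, dtype=float)[order]
    cum_tp = np.cumsum(tp_s)
    cum_fp = np.cumsum(~tp_s)
    recall = cum_tp / max(n_gt, 1)
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1)
    ap = average_precision(tp, conf, n_gt)
    return PRCurve(recall, precision, conf_s, ap)


def evaluate(gts_per_image: Sequence[Sequence[Box]],
             preds_per_image: Sequence[Sequence[Box]],
             class_names: Sequence[str],
             iou_thresh: float = 0.5,
             cm_iou_thresh: float = 0.45,
             cm_conf_thresh: float = 0.25) -> EvalReport:
    """Evaluate predictions against ground truth, image by image.

    AP50 is computed per class over the pooled confidence sweep; mAP50
    averages classes present in the ground truth (absent classes are excluded
    and reported).  Scalar precision/recall are quoted at the confidence
    threshold maximizing F1 over the pooled sweep.
    """
    n_classes = len(class_names)
    if len(gts_per_image) != len(preds_per_image):
        raise ValueError("gts and preds must cover the same images")
    tp_all: dict[int, list] = {c: [] for c in range(n_classes)}
    conf_all: dict[int, list] = {c: [] for c in range(n_classes)}
    n_gt = np.zeros(n_classes, dtype=int)
    cm = np.zeros((n_classes + 1, n_classes + 1), dtype=int)
    for gts, preds in zip(gts_per_image, preds_per_image):
        match = match_detections(preds, gts, iou_thresh)
        for c in range(n_classes):
            sel = match.pred_cls == c
            tp_all[c].extend(match.tp[sel].tolist())
            conf_all[c].extend(match.conf[sel].tolist())
        for gt in gts:
            n_gt[gt.cls] += 1
        cm += confusion_matrix(preds, gts, n_classes, cm_iou_thresh, cm_conf_thresh)

    curves: dict[str, PRCurve] = {}
    per_class_ap: dict[str, float] = {}
    absent: list[str] = []
    aps: list[float] = []
    for c, name in enumerate(class_names):
        if n_gt[c] == 0:
            absent.append(name)
            logger.info("class %r absent from ground truth; excluded from mAP", name)
            continue
        curve = _pr_curve(np.array(tp_all[c], dtype=bool),
                          np.array(conf_all[c], dtype=float), int(n_gt[c]))
        curves[name] = curve
        per_class_ap[name] = curve.ap
        aps.append(curve.ap)

    # pooled sweep for the max-F1 operating point
    pooled_tp = np.concatenate([np.array(tp_all[c], dtype=bool)
                                for c in range(n_classes)]) if n_classes else np.array([])
    pooled_conf = np.concatenate([np.array(conf_all[c], dtype=float)
                                  for c in range(n_classes)]) if n_classes else np.array([])
    total_gt = int(n_gt.sum())
    if pooled_tp.size and total_gt:
        order = np.lexsort((np.arange(len(pooled_conf)), -pooled_conf))
        tp_s, conf_s = pooled_tp[order], pooled_conf[order]
        cum_tp = np.cumsum(tp_s)
        cum_fp = np.cumsum(~tp_s)
        prec = cum_tp / np.maximum(cum_tp + cum_fp, 1)
        rec = cum_tp / total_gt
        f1 = 2 * prec * rec / np.maximum(prec + rec, 1e-12)
        k = int(np.argmax(f1))
        best_p, best_r, best_t = float(prec[k]), float(rec[k]), float(conf_s[k])
    else:
        best_p, best_r, best_t = 0.0, (1.0 if total_gt == 0 else 0.0), 0.0

    return EvalReport(list(class_names), per_class_ap, map50(aps),
                      best_p, best_r, best_t, curves, cm, absent)


def map50_95(gts_per_image: Sequence[Sequence[Box]],
             preds_per_image: Sequence[Sequence[Box]],
             class_names: Sequence[str]) -> float:
    """COCO-style mean AP over IoU thresholds 0.50:0.05:0.95.

    Secondary metric; the headline remains mAP50.
    """
    thresholds = np.arange(0.5, 0.96, 0.05)
    maps = [evaluate(gts_per_image, preds_per_image, class_names,
                     iou_thresh=float(t)).map50 for t in thresholds]
    return float(np.mean(maps))


def evaluate_dirs(manifest: DatasetManifest, predictions_dir: str | Path,
                  **kwargs) -> EvalReport:
    """Evaluate a predictions directory (YOLO txt + confidence column)."""
    predictions_dir = Path(predictions_dir)
    gts, preds = [], []
    for lab in manifest.label_paths:
        gts.append(read_yolo_labels(lab, n_classes=len(manifest.names)))
        pred_file = predictions_dir / lab.name
        if pred_file.exists():
            preds.append(read_yolo_labels(pred_file, n_classes=len(manifest.names)))
        else:
            preds.append([])
    return evaluate(gts, preds, manifest.names, **kwargs)


def plot_pr_curves(report: EvalReport, path: str | Path) -> None:
    """Render per-class P-R curves to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in report.curves.items():
        ax.plot(curve.recall, curve.precision,
                label=f"{name} (AP50={curve.ap:.3f})")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    ax.set_title(f"mAP50 = {report.map50:.3f}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
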