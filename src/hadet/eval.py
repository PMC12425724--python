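"""Detection evaluation: per-class average precision and mAP.

AP follows the COCO-style protocol: detections are matched to ground truth
greedily in descending confidence order (best remaining IoU, one match per
ground-truth box, per image and class), precision is interpolated onto 101
evenly spaced recall points through the running-maximum envelope, and mAP is
averaged over the classes that occur in the ground truth.  ``mAP50`` uses an
IoU threshold of 0.5; ``mAP50_95`` averages thresholds 0.50:0.05:0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidConfigError
from .losses import iou_matrix
from .train_eval import Detection

__all__ = ["EvalResult", "average_precision", "evaluate_map", "IOU_THRESHOLDS"]

IOU_THRESHOLDS = np.round(np.arange(0.50, 0.96, 0.05), 2)
RECALL_POINTS = np.linspace(0.0, 1.0, 101)


@dataclass
class EvalResult:
    ap50: dict[int, float]
    map50: float
    map50_95: float
    per_threshold: dict[float, float] = field(default_factory=dict)
    pr_curves: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def summary(self) -> str:
        per_cls = ", ".join(f"class {c}: {v:.3f}" for c, v in sorted(self.ap50.items()))
        return (
            f"mAP50 {self.map50:.4f} | mAP50-95 {self.map50_95:.4f} | AP50 {per_cls}"
        )


def _match_stats(dets: list[tuple[int, float, np.ndarray]],
                 gts: dict[int, np.ndarray], iou_thr: float
                 ) -> tuple[np.ndarray, np.ndarray, int]:
    """Greedy confidence-ordered matching for one class.

    ``dets``: (image_id, confidence, box) tuples; ``gts``: image_id -> (M,4).
    Returns cumulative TP/FP indicator arrays in confidence order plus the
    ground-truth count.
    """
    n_gt = sum(len(v) for v in gts.values())
    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
    matched: dict[int, np.ndarray] = {
        img: np.zeros(len(v), dtype=bool) for img, v in gts.items()
    }
    tp = np.zeros(len(dets))
    fp = np.zeros(len(dets))
    for rank, i in enumerate(order):
        img, _, box = dets[i]
        gt_boxes = gts.get(img)
        if gt_boxes is None or not len(gt_boxes):
            fp[rank] = 1
            continue
        ious = iou_matrix(box.reshape(1, 4), gt_boxes)[0]
        ious[matched[img]] = -1.0
        j = int(ious.argmax())
        if ious[j] >= iou_thr:
            tp[rank] = 1
            matched[img][j] = True
        else:
            fp[rank] = 1
    return tp, fp, n_gt


def average_precision(tp: np.ndarray, fp: np.ndarray, n_gt: int
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """101-point interpolated AP from per-detection TP/FP indicators."""
    if n_gt == 0:
        return float("nan"), np.zeros(0), np.zeros(0)
    if len(tp) == 0:
        return 0.0, np.zeros(0), np.zeros(0)
    ctp, cfp = np.cumsum(tp), np.cumsum(fp)
    recall = ctp / n_gt
    precision = ctp / np.maximum(ctp + cfp, 1e-12)
    # running-maximum precision envelope, then sample the recall grid
    env = np.maximum.accumulate(precision[::-1])[::-1]
    idx = np.searchsorted(recall, RECALL_POINTS, side="left")
    interp = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
    return float(interp.mean()), recall, precision


def evaluate_map(detections: list[list[Detection]],
                 ground_truth: list[dict], num_classes: int) -> EvalResult:
    """Evaluate per-image detection lists against per-image ground truth.

    ``ground_truth[i]`` maps 'boxes' to an (M, 4) corner-format array and
    'classes' to (M,) integer labels.
    """
    if len(detections) != len(ground_truth):
        raise InvalidConfigError(
            f"{len(detections)} detection lists vs {len(ground_truth)} images"
        )
    per_class_dets: dict[int, list] = {c: [] for c in range(num_classes)}
    per_class_gts: dict[int, dict[int, np.ndarray]] = {c: {} for c in range(num_classes)}
    for img_id, (dets, gt) in enumerate(zip(detections, ground_truth)):
        classes = np.asarray(gt["classes"], dtype=np.int64)
        boxes = np.asarray(gt["boxes"], dtype=np.float64).reshape(-1, 4)
        if classes.size and (classes.min() < 0 or classes.max() >= num_classes):
            raise InvalidConfigError(
                f"image {img_id}: class ids outside 0..{num_classes - 1}"
            )
        for c in range(num_classes):
            sel = boxes[classes == c]
            if len(sel):
                per_class_gts[c][img_id] = sel
        for d in dets:
            if not 0 <= d.class_id < num_classes:
                raise InvalidConfigError(f"detection class {d.class_id} out of range")
            per_class_dets[d.class_id].append(
                (img_id, d.confidence, np.array(d.xyxy))
            )

    ap50: dict[int, float] = {}
    pr_curves = {}
    per_threshold: dict[float, float] = {}
    ap_grid: dict[float, list[float]] = {float(t): [] for t in IOU_THRESHOLDS}
    for c in range(num_classes):
        if not per_class_gts[c]:
            continue  # class absent from ground truth: skipped, not zero
        for t in IOU_THRESHOLDS:
            tp, fp, n_gt = _match_stats(per_class_dets[c], per_class_gts[c], float(t))
            ap, recall, precision = average_precision(tp, fp, n_gt)
            ap_grid[float(t)].append(ap)
            if abs(t - 0.5) < 1e-9:
                ap50[c] = ap
                pr_curves[c] = (recall, precision)
    if not ap50:
        raise InvalidConfigError("no ground-truth boxes to evaluate against")
    for t, vals in ap_grid.items():
        per_threshold[t] = float(np.mean(vals))
    map50 = per_threshold[0.5]
    map50_95 = float(np.mean(list(per_threshold.values())))
    return EvalResult(ap50, map50, map50_95, per_threshold, pr_curves)
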