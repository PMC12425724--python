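"""Micro training harness: target assignment, the three-term loss, an SGD
loop with warmup, and prediction with non-maximum suppression.

The head is anchor-free: every feature-map cell center at strides 8/16/32 is
a candidate ("anchor point"; 8,400 at 640x640 input).  Assignment is a
deliberately simple, enumerable rule: an anchor is positive iff its point
lies inside a ground-truth box *and* the box's longer side falls in the
stride's pixel range (stride 8 up to 64 px, stride 16 up to 128 px, stride
32 above); when several boxes claim one anchor the smallest area wins.  Each
positive anchor regresses its four side distances as discrete distributions
over ``reg_max`` bins (decoded by softmax expectation) and is supervised by
CIoU or its hook reweighting plus the distribution focal loss; every anchor
contributes per-class binary cross-entropy, which also plays the confidence
role in this decoupled-head family.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .architecture import REG_MAX, STRIDES, ModelSpec, build_variant
from .data import DatasetManifest, load_split
from .exceptions import InvalidConfigError
from .losses import (
    Box,
    HookParams,
    LossWeights,
    box_regression_loss_t,
    iou_matrix,
)
from .network import DetectionModel, instantiate
from .nn import SGD, Tensor, no_grad

__all__ = [
    "TrainConfig",
    "Detection",
    "VARIANTS",
    "build_model",
    "make_anchors",
    "assign_targets",
    "compute_loss",
    "train",
    "predict",
    "nms",
    "save_checkpoint",
    "load_checkpoint",
]

# pixel range of a box's longer side handled by each stride
SCALE_RANGES = {8: (0.0, 64.0), 16: (64.0, 128.0), 32: (128.0, float("inf"))}

VARIANTS = {
    "baseline": {},
    "shuffle3d": {"shuffle3d_heads": True},
    "dualchannel": {"dual_channel": True},
    "spatial": {"spatial_input": True},
    "ha": {"dual_channel": True, "shuffle3d_heads": True, "spatial_input": True},
}


def build_model(name: str, num_classes: int = 4, seed: int = 0,
                input_size: int = 640) -> DetectionModel:
    if name not in VARIANTS:
        raise InvalidConfigError(f"unknown model {name!r}; choose from {sorted(VARIANTS)}")
    spec = build_variant(num_classes, input_size=input_size, **VARIANTS[name])
    spec.name = name
    return instantiate(spec, seed=seed)


@dataclass
class TrainConfig:
    """Optimizer and schedule settings; the optimizer hyperparameters follow
    the reference training recipe (SGD, lr 0.01, momentum 0.937, weight
    decay 5e-4), sized down to a desk-scale run."""

    epochs: int = 20
    batch_size: int = 8
    lr0: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    imgsz: int = 96
    seed: int = 0
    model: str = "ha"
    num_classes: int = 4
    box_loss: str = "ciou"  # or "hkciou"
    hook_a: float = 0.5
    hook_b: float = 0.5
    hook_mode: str = "loss"
    w_box: float = 7.5
    w_dfl: float = 1.5
    w_cls: float = 0.5
    warmup_epochs: int = 3
    hflip: bool = True
    value_jitter: float = 0.1  # multiplicative brightness jitter amplitude

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.lr0 < 0:
            raise InvalidConfigError("epochs/batch must be positive, lr nonnegative")
        if self.imgsz % 32:
            raise InvalidConfigError("image size must be divisible by 32")

    @property
    def hook(self) -> HookParams:
        return HookParams(self.hook_a, self.hook_b, self.hook_mode)

    @property
    def weights(self) -> LossWeights:
        return LossWeights(self.w_box, self.w_dfl, self.w_cls)


@dataclass(frozen=True)
class Detection:
    box: Box
    class_id: int
    confidence: float

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidConfigError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def xyxy(self) -> tuple[float, float, float, float]:
        return self.box.corners


# ---------------------------------------------------------------------------
# anchors and assignment
# ---------------------------------------------------------------------------


def make_anchors(imgsz: int) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center points and their strides for the three scales."""
    pts, sts = [], []
    for s in STRIDES:
        n = imgsz // s
        c = (np.arange(n) + 0.5) * s
        gx, gy = np.meshgrid(c, c)
        pts.append(np.stack([gx.ravel(), gy.ravel()], axis=1))
        sts.append(np.full(n * n, s, dtype=np.float64))
    return np.concatenate(pts), np.concatenate(sts)


def assign_targets(points: np.ndarray, strides: np.ndarray,
                   gt_boxes: np.ndarray, gt_classes: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Positive-anchor selection.

    Returns ``(anchor_idx, gt_idx)``: the indices of positive anchors and the
    ground-truth box assigned to each.  No ground truth yields two empty
    arrays.
    """
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    if len(gt_boxes) == 0:
        empty = np.zeros(0, dtype=np.int64)
        return empty, empty
    px, py = points[:, 0:1], points[:, 1:2]  # (A,1)
    inside = (
        (px >= gt_boxes[None, :, 0].reshape(1, -1))
        & (px < gt_boxes[None, :, 2].reshape(1, -1))
        & (py >= gt_boxes[None, :, 1].reshape(1, -1))
        & (py < gt_boxes[None, :, 3].reshape(1, -1))
    )
    long_side = np.maximum(gt_boxes[:, 2] - gt_boxes[:, 0],
                           gt_boxes[:, 3] - gt_boxes[:, 1])
    lo = np.array([SCALE_RANGES[int(s)][0] for s in strides])
    hi = np.array([SCALE_RANGES[int(s)][1] for s in strides])
    in_range = (long_side[None, :] > lo[:, None]) & (long_side[None, :] <= hi[:, None])
    cand = inside & in_range
    area = (gt_boxes[:, 2] - gt_boxes[:, 0]) * (gt_boxes[:, 3] - gt_boxes[:, 1])
    # smallest-area tie-break among claiming boxes
    cost = np.where(cand, area[None, :], np.inf)
    gt_idx = cost.argmin(axis=1)
    pos = cand.any(axis=1)
    anchor_idx = np.nonzero(pos)[0]
    return anchor_idx.astype(np.int64), gt_idx[pos].astype(np.int64)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def _flatten_outputs(outputs: list[tuple[Tensor, Tensor]], nc: int
                     ) -> tuple[Tensor, Tensor]:
    """Concatenate per-scale head outputs to (B, 4, reg_max, A) and (B, nc, A)."""
    box_parts, cls_parts = [], []
    for box, cls in outputs:
        b, _, h, w = box.shape
        box_parts.append(box.reshape(b, 4, REG_MAX, h * w))
        cls_parts.append(cls.reshape(b, nc, h * w))
    return Tensor.concat(box_parts, axis=3), Tensor.concat(cls_parts, axis=2)


def compute_loss(outputs: list[tuple[Tensor, Tensor]],
                 targets: list[dict], cfg: TrainConfig,
                 points: np.ndarray, strides: np.ndarray
                 ) -> tuple[Tensor, dict]:
    """Batch loss; ``targets[i]`` holds pixel 'boxes' (M,4) and 'classes'."""
    nc = cfg.num_classes
    box_out, cls_out = _flatten_outputs(outputs, nc)
    bsz, _, _, num_anchors = box_out.shape

    b_idx, a_idx, t_boxes, t_cls = [], [], [], []
    for i, t in enumerate(targets):
        ai, gi = assign_targets(points, strides, t["boxes"], t["classes"])
        if len(ai) == 0:
            continue
        b_idx.append(np.full(len(ai), i))
        a_idx.append(ai)
        t_boxes.append(np.asarray(t["boxes"], dtype=np.float64)[gi])
        t_cls.append(np.asarray(t["classes"], dtype=np.int64)[gi])
    n_pos = sum(len(a) for a in a_idx)

    cls_target = np.zeros((bsz, nc, num_anchors), dtype=np.float32)
    if n_pos:
        b_idx = np.concatenate(b_idx)
        a_idx = np.concatenate(a_idx)
        t_boxes = np.concatenate(t_boxes)
        t_cls = np.concatenate(t_cls)
        cls_target[b_idx, t_cls, a_idx] = 1.0

        pts = points[a_idx]
        sts = strides[a_idx]
        dist = box_out[b_idx, :, :, a_idx]          # (n_pos, 4, reg_max)
        prob = dist.softmax(axis=-1)
        bins = np.arange(REG_MAX, dtype=np.float64)
        ltrb = (prob * bins.reshape(1, 1, -1)).sum(axis=-1)  # stride units
        sx = sts.reshape(-1, 1)
        px, py = pts[:, 0].reshape(-1, 1), pts[:, 1].reshape(-1, 1)
        x1 = px - ltrb[:, 0].reshape(-1, 1) * sx
        y1 = py - ltrb[:, 1].reshape(-1, 1) * sx
        x2 = px + ltrb[:, 2].reshape(-1, 1) * sx
        y2 = py + ltrb[:, 3].reshape(-1, 1) * sx
        pred_boxes = Tensor.concat([x1, y1, x2, y2], axis=1)
        l_box = box_regression_loss_t(
            pred_boxes, Tensor(t_boxes), cfg.box_loss, cfg.hook
        ).mean()

        # distribution focal loss on the two neighbouring bins
        tl = np.stack([
            (pts[:, 0] - t_boxes[:, 0]), (pts[:, 1] - t_boxes[:, 1]),
            (t_boxes[:, 2] - pts[:, 0]), (t_boxes[:, 3] - pts[:, 1]),
        ], axis=1) / sts.reshape(-1, 1)
        tl = np.clip(tl, 0.0, REG_MAX - 1 - 1e-3)
        left = np.minimum(np.floor(tl), REG_MAX - 2).astype(np.int64)
        wl = left + 1 - tl
        wr = tl - left
        n_i, s_i = np.indices(left.shape)
        p_l = prob[n_i.ravel(), s_i.ravel(), left.ravel()]
        p_r = prob[n_i.ravel(), s_i.ravel(), (left + 1).ravel()]
        eps = 1e-9
        l_dfl = -(
            (p_l + eps).log() * wl.ravel() + (p_r + eps).log() * wr.ravel()
        ).mean()
    else:
        l_box = Tensor(np.float32(0.0))
        l_dfl = Tensor(np.float32(0.0))

    # per-class BCE over every anchor, normalized by the positive count
    z = cls_target
    logits = cls_out
    pos_part = logits.clip(0.0, np.inf)
    neg_abs = (logits * -1.0).clip(0.0, np.inf)
    bce = pos_part - logits * z + (1.0 + ((pos_part + neg_abs) * -1.0).exp()).log()
    l_cls = bce.sum() * (1.0 / max(n_pos, 1))

    total = l_box * cfg.w_box + l_dfl * cfg.w_dfl + l_cls * cfg.w_cls
    parts = {
        "box": float(l_box.data),
        "dfl": float(l_dfl.data),
        "cls": float(l_cls.data),
        "total": float(total.data),
        "n_pos": int(n_pos),
    }
    return total, parts


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _augment(img: np.ndarray, boxes: np.ndarray, cfg: TrainConfig,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if cfg.hflip and rng.random() < 0.5:
        img = img[:, :, ::-1].copy()
        w = img.shape[2]
        boxes = boxes.copy()
        boxes[:, [0, 2]] = w - boxes[:, [2, 0]]
    if cfg.value_jitter:
        img = np.clip(img * rng.uniform(1 - cfg.value_jitter, 1 + cfg.value_jitter),
                      0.0, 1.0).astype(np.float32)
    return img, boxes


@dataclass
class TrainResult:
    model: DetectionModel
    history: list[dict] = field(default_factory=list)
    config: TrainConfig | None = None


def train(manifest: DatasetManifest, cfg: TrainConfig,
          model: DetectionModel | None = None,
          log: callable = None) -> TrainResult:
    """SGD training on the manifest's train split.

    Deterministic given ``cfg.seed``; raises on divergence (non-finite loss).
    """
    samples = load_split(manifest, "train")
    if not samples:
        raise InvalidConfigError("train split is empty")
    size = samples[0]["image"].shape[1]
    if size % 32:
        raise InvalidConfigError(f"image size {size} not divisible by 32")
    if model is None:
        model = build_model(cfg.model, cfg.num_classes, seed=cfg.seed,
                            input_size=size)
    model.train()
    opt = SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    points, strides = make_anchors(size)
    rng = np.random.default_rng(cfg.seed)
    steps_per_epoch = math.ceil(len(samples) / cfg.batch_size)
    warmup_steps = max(1, cfg.warmup_epochs * steps_per_epoch)
    history: list[dict] = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(samples))
        epoch_parts: list[dict] = []
        for start in range(0, len(samples), cfg.batch_size):
            batch = [samples[i] for i in order[start : start + cfg.batch_size]]
            imgs, tgts = [], []
            for s in batch:
                img, boxes = _augment(s["image"], s["boxes"], cfg, rng)
                imgs.append(img)
                tgts.append({"boxes": boxes, "classes": s["classes"]})
            x = Tensor(np.stack(imgs))
            opt.lr = cfg.lr0 * min(1.0, (step + 1) / warmup_steps)
            outputs = model(x)
            loss, parts = compute_loss(outputs, tgts, cfg, points, strides)
            if not math.isfinite(parts["total"]):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss {parts['total']}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_parts.append(parts)
            step += 1
        mean = {
            k: float(np.mean([p[k] for p in epoch_parts]))
            for k in ("box", "dfl", "cls", "total")
        }
        mean["epoch"] = epoch
        history.append(mean)
        if log is not None:
            log(mean)
    return TrainResult(model, history, cfg)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float = 0.7) -> np.ndarray:
    """Greedy suppression; returns kept indices in descending score order."""
    order = np.argsort(-scores)
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    ious = iou_matrix(boxes, boxes) if len(boxes) else None
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        suppressed |= ious[i] > iou_thr
        suppressed[i] = True  # mark handled (kept)
    return np.array(keep, dtype=np.int64)


def predict(model: DetectionModel, images: np.ndarray | list[np.ndarray],
            conf_threshold: float = 0.25, nms_iou: float = 0.7,
            batch_size: int = 8) -> list[list[Detection]]:
    """Decode detections for (lists of) CHW float images in [0, 1]."""
    if isinstance(images, np.ndarray) and images.ndim == 3:
        images = [images]
    model.eval()
    results: list[list[Detection]] = []
    bins = np.arange(REG_MAX, dtype=np.float32)
    for start in range(0, len(images), batch_size):
        chunk = np.stack(images[start : start + batch_size])
        size = chunk.shape[2]
        points, strides = make_anchors(size)
        with no_grad():
            outputs = model(Tensor(chunk))
        box_out, cls_out = _flatten_outputs(outputs, model.num_classes)
        dist = box_out.numpy()  # (B, 4, reg_max, A)
        e = np.exp(dist - dist.max(axis=2, keepdims=True))
        prob = e / e.sum(axis=2, keepdims=True)
        ltrb = np.einsum("bsra,r->bsa", prob, bins)  # (B, 4, A)
        px, py = points[:, 0], points[:, 1]
        x1 = px - ltrb[:, 0] * strides
        y1 = py - ltrb[:, 1] * strides
        x2 = px + ltrb[:, 2] * strides
        y2 = py + ltrb[:, 3] * strides
        boxes = np.stack([x1, y1, x2, y2], axis=-1)  # (B, A, 4)
        scores = 1.0 / (1.0 + np.exp(-cls_out.numpy()))  # (B, nc, A)
        for bi in range(len(chunk)):
            dets: list[Detection] = []
            for c in range(model.num_classes):
                sc = scores[bi, c]
                mask = sc >= conf_threshold
                if not mask.any():
                    continue
                cand_boxes = np.clip(boxes[bi][mask], 0, size)
                cand_scores = sc[mask]
                valid = (cand_boxes[:, 2] > cand_boxes[:, 0]) & (
                    cand_boxes[:, 3] > cand_boxes[:, 1]
                )
                cand_boxes, cand_scores = cand_boxes[valid], cand_scores[valid]
                if not len(cand_boxes):
                    continue
                for k in nms(cand_boxes, cand_scores, nms_iou):
                    bx = cand_boxes[k]
                    dets.append(Detection(
                        Box.from_corners(*bx), c, float(cand_scores[k])
                    ))
            dets.sort(key=lambda d: -d.confidence)
            results.append(dets)
    return results


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(result: TrainResult, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "model": result.config.model if result.config else "ha",
        "num_classes": result.model.num_classes,
        "history": result.history,
        "config": asdict(result.config) if result.config else None,
    }
    arrays = result.model.state_arrays()
    np.savez_compressed(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> TrainResult:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    model = build_model(meta["model"], meta["num_classes"])
    model.load_state_arrays(arrays)
    cfg = TrainConfig(**meta["config"]) if meta.get("config") else None
    return TrainResult(model, meta.get("history", []), cfg)
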