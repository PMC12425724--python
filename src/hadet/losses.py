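"""Bounding-box regression losses: IoU, CIoU, the hook reweighting (HKCIoU),
distribution focal loss, and the three-term detection total.

CIoU extends IoU with a normalized center-distance penalty and an
aspect-ratio consistency penalty::

    CIoU = IoU - rho^2(b_p, b_t) / c^2 - alpha * v
    v     = (4 / pi^2) (arctan(w_t / h_t) - arctan(w_p / h_p))^2
    alpha = v / (1 - IoU + v)

where ``rho`` is the center distance and ``c`` the diagonal of the smallest
enclosing box.  The hook function ``f(x) = a*x + b/x`` (convex on x > 0 with
its minimum at sqrt(b/a), i.e. exactly 1 for the default a = b = 0.5)
reweights the CIoU loss ``L = 1 - CIoU``::

    HKCIoU = f(L) * L = a * L^2 + b

so poor boxes (L > 1) see an amplified loss and gradient while good boxes
(L < 1) see a damped one.  The product form is evaluated as the algebraic
identity ``a*L^2 + b``, which is finite at L = 0 (value b).

Scalar entry points operate on :class:`Box`; ``*_t`` variants operate on
``(N, 4)`` corner-format tensors and are differentiable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, InvalidBoxError, InvalidConfigError
from .nn import Tensor

__all__ = [
    "Box",
    "CIoUBreakdown",
    "HookParams",
    "LossWeights",
    "LossBreakdown",
    "iou",
    "ciou",
    "hook",
    "hkciou_loss",
    "dfl_loss",
    "total_loss",
    "iou_matrix",
    "pairwise_ciou_t",
    "box_regression_loss_t",
    "bce_with_logits_t",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, center/extent convention; extents strictly positive."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"box extents must be positive, got w={self.w}, h={self.h}")

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float) -> "Box":
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)

    @property
    def corners(self) -> tuple[float, float, float, float]:
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class CIoUBreakdown:
    iou: float
    center_term: float        # rho^2 / c^2
    aspect_v: float           # aspect-ratio consistency penalty v
    alpha_tradeoff: float     # trade-off weight on v
    ciou: float


@dataclass(frozen=True)
class HookParams:
    """Hyperparameters of the hook reweighting; default a = b = 0.5 puts the
    hook's minimum at x = 1."""

    a: float = 0.5
    b: float = 0.5
    mode: str = "loss"  # reweight the CIoU loss (1 - CIoU) or the raw value

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise InvalidConfigError(f"hook needs a, b > 0, got a={self.a}, b={self.b}")
        if self.mode not in ("loss", "metric"):
            raise InvalidConfigError(f"mode must be 'loss' or 'metric', got {self.mode!r}")

    @property
    def minimizer(self) -> float:
        return math.sqrt(self.b / self.a)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the three-term total; the confidence weight is retained as
    an alias even though objectness is folded into the per-class term in the
    anchor-free head (see the methods note)."""

    w_box: float = 7.5
    w_obj: float = 1.5
    w_cls: float = 0.5

    def __post_init__(self):
        if min(self.w_box, self.w_obj, self.w_cls) < 0:
            raise InvalidConfigError("loss weights must be nonnegative")
        if self.w_box == self.w_obj == self.w_cls == 0:
            raise InvalidConfigError("at least one loss weight must be positive")


@dataclass(frozen=True)
class LossBreakdown:
    l_box: float
    l_obj: float
    l_cls: float
    total: float


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------


def iou(p: Box, t: Box) -> float:
    """Intersection over union; symmetric, 0 for disjoint boxes."""
    px1, py1, px2, py2 = p.corners
    tx1, ty1, tx2, ty2 = t.corners
    iw = min(px2, tx2) - max(px1, tx1)
    ih = min(py2, ty2) - max(py1, ty1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (p.area + t.area - inter)


def ciou(p: Box, t: Box) -> CIoUBreakdown:
    """Complete IoU with its full term-by-term decomposition."""
    i = iou(p, t)
    px1, py1, px2, py2 = p.corners
    tx1, ty1, tx2, ty2 = t.corners
    cw = max(px2, tx2) - min(px1, tx1)
    ch = max(py2, ty2) - min(py1, ty1)
    rho2 = (p.cx - t.cx) ** 2 + (p.cy - t.cy) ** 2
    c2 = cw * cw + ch * ch
    center = rho2 / c2 if c2 > 0 else 0.0
    v = (4.0 / math.pi**2) * (
        math.atan(t.w / t.h) - math.atan(p.w / p.h)
    ) ** 2
    denom = 1.0 - i + v
    alpha = v / denom if denom > 0 else 0.0
    return CIoUBreakdown(i, center, v, alpha, i - center - alpha * v)


def hook(x: float, hp: HookParams = HookParams()) -> float:
    """``a*x + b/x`` on x > 0; strictly convex, minimized at sqrt(b/a)."""
    if x <= 0:
        raise DomainError(f"hook is defined on x > 0, got {x}")
    return hp.a * x + hp.b / x


def hkciou_loss(p: Box, t: Box, hp: HookParams = HookParams()) -> float:
    """Hook-reweighted CIoU, evaluated as ``a*x^2 + b``.

    In the default ``loss`` mode x is the CIoU loss ``1 - CIoU``; in
    ``metric`` mode the reweighting is applied to the CIoU value itself.
    """
    c = ciou(p, t).ciou
    x = 1.0 - c if hp.mode == "loss" else c
    return hp.a * x * x + hp.b


def dfl_loss(pred_distribution: np.ndarray, target_offset: float,
             atol: float = 1e-6) -> float:
    """Distribution focal loss for one box side.

    ``pred_distribution`` is a probability vector over ``reg_max`` integer
    bins; the continuous target in ``[0, reg_max - 1]`` is supervised through
    its two neighbouring bins with linear weights.
    """
    prob = np.asarray(pred_distribution, dtype=np.float64)
    if prob.ndim != 1 or prob.size < 2:
        raise DomainError("distribution must be a vector of >= 2 bins")
    if abs(prob.sum() - 1.0) > 1e-4 or (prob < -atol).any():
        raise DomainError("distribution must be nonnegative and sum to 1")
    reg_max = prob.size
    t = float(target_offset)
    if not 0.0 <= t <= reg_max - 1:
        raise DomainError(f"target {t} outside [0, {reg_max - 1}]")
    left = min(int(math.floor(t)), reg_max - 2)
    wl, wr = left + 1 - t, t - left
    eps = 1e-12
    return -(wl * math.log(prob[left] + eps) + wr * math.log(prob[left + 1] + eps))


def total_loss(lb: float, lo: float, lc: float,
               w: LossWeights = LossWeights()) -> LossBreakdown:
    """Weighted three-term total (box + confidence + classification)."""
    terms = (lb, lo, lc)
    if any(not math.isfinite(v) for v in terms):
        raise InvalidConfigError(f"loss terms must be finite, got {terms}")
    if any(v < 0 for v in terms):
        raise InvalidConfigError(f"loss terms must be nonnegative, got {terms}")
    return LossBreakdown(lb, lo, lc, w.w_box * lb + w.w_obj * lo + w.w_cls * lc)


# ---------------------------------------------------------------------------
# batched / differentiable forms
# ---------------------------------------------------------------------------


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two corner-format box arrays, shapes (N,4) and (M,4)."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0.0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def pairwise_ciou_t(pred: Tensor, target: Tensor, eps: float = 1e-9) -> Tensor:
    """Elementwise CIoU of matched corner-format boxes, differentiable.

    ``pred`` carries gradient; ``target`` is treated as constant.
    """
    px1, py1, px2, py2 = (pred[:, i] for i in range(4))
    t = target.data if isinstance(target, Tensor) else np.asarray(target)
    tx1, ty1, tx2, ty2 = (Tensor(t[:, i]) for i in range(4))

    def _min(a, b):
        return a - (a - b).clip(0.0, np.inf)

    def _max(a, b):
        return a + (b - a).clip(0.0, np.inf)

    iw = (_min(px2, tx2) - _max(px1, tx1)).clip(0.0, np.inf)
    ih = (_min(py2, ty2) - _max(py1, ty1)).clip(0.0, np.inf)
    inter = iw * ih
    area_p = (px2 - px1) * (py2 - py1)
    area_t = (tx2 - tx1) * (ty2 - ty1)
    union = area_p + area_t - inter + eps
    i = inter / union
    cw = _max(px2, tx2) - _min(px1, tx1)
    ch = _max(py2, ty2) - _min(py1, ty1)
    c2 = cw * cw + ch * ch + eps
    rho2 = ((px1 + px2 - tx1 - tx2) ** 2.0 + (py1 + py2 - ty1 - ty2) ** 2.0) * 0.25
    v = (
        ((tx2 - tx1) / (ty2 - ty1 + eps)).arctan()
        - ((px2 - px1) / (py2 - py1 + eps)).arctan()
    ) ** 2.0 * (4.0 / math.pi**2)
    alpha = v / (1.0 - i + v + eps)
    return i - rho2 / c2 - alpha * v


def box_regression_loss_t(pred: Tensor, target: Tensor,
                          kind: str = "ciou",
                          hp: HookParams = HookParams()) -> Tensor:
    """Per-box regression loss: plain CIoU loss or its hook reweighting."""
    c = pairwise_ciou_t(pred, target)
    if kind == "ciou":
        return 1.0 - c
    if kind == "hkciou":
        x = (1.0 - c) if hp.mode == "loss" else c
        return x * x * hp.a + hp.b
    raise InvalidConfigError(f"unknown box loss kind {kind!r}")


def bce_with_logits_t(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy on logits (mean over elements)."""
    z = np.asarray(targets)
    # softplus(x) - x*z, with softplus(x) = max(x,0) + log(1 + exp(-|x|))
    pos = logits.clip(0.0, np.inf)
    neg = (logits * -1.0).clip(0.0, np.inf)
    loss = pos - logits * z + (1.0 + ((pos + neg) * -1.0).exp()).log()
    return loss.mean()
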