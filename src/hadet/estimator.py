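"""Scikit-learn style estimator facade over the detector.

``TumorDetector`` exposes the train/predict/evaluate pipeline with the
standard estimator contract: constructor parameters mirror
:class:`~hadet.train_eval.TrainConfig`, ``fit`` accepts a dataset manifest
(or a path to its YAML), fitted state lives in trailing-underscore
attributes, and ``get_params``/``set_params``/``clone`` work through
:class:`sklearn.base.BaseEstimator`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import DatasetManifest, load_split
from .eval import EvalResult, evaluate_map
from .train_eval import Detection, TrainConfig, predict, train

__all__ = ["TumorDetector"]


class TumorDetector(BaseEstimator):
    """Single-stage tumor detector with attention variants and IoU-family
    box losses.

    Parameters mirror the training configuration; see the methods note for
    their meaning and defaults.  After ``fit``:

    ``model_``
        the trained network,
    ``loss_history_``
        per-epoch mean loss components,
    ``config_``
        the resolved :class:`TrainConfig`.
    """

    def __init__(self, model: str = "ha", box_loss: str = "hkciou",
                 epochs: int = 20, batch_size: int = 8, lr0: float = 0.01,
                 momentum: float = 0.937, weight_decay: float = 0.0005,
                 imgsz: int = 96, num_classes: int = 4, seed: int = 0,
                 hook_a: float = 0.5, hook_b: float = 0.5,
                 conf_threshold: float = 0.25, nms_iou: float = 0.7):
        self.model = model
        self.box_loss = box_loss
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.imgsz = imgsz
        self.num_classes = num_classes
        self.seed = seed
        self.hook_a = hook_a
        self.hook_b = hook_b
        self.conf_threshold = conf_threshold
        self.nms_iou = nms_iou

    def _config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size, lr0=self.lr0,
            momentum=self.momentum, weight_decay=self.weight_decay,
            imgsz=self.imgsz, seed=self.seed, model=self.model,
            num_classes=self.num_classes, box_loss=self.box_loss,
            hook_a=self.hook_a, hook_b=self.hook_b,
        )

    @staticmethod
    def _manifest(X) -> DatasetManifest:
        if isinstance(X, DatasetManifest):
            return X
        return DatasetManifest.load(Path(X))

    def fit(self, X, y=None) -> "TumorDetector":
        """Train on the manifest's train split.

        ``X`` is a :class:`DatasetManifest` or a path to a dataset YAML; the
        labels live next to the images, so ``y`` is ignored.
        """
        cfg = self._config()
        result = train(self._manifest(X), cfg)
        self.model_ = result.model
        self.loss_history_ = result.history
        self.config_ = cfg
        return self

    def predict(self, X) -> list[list[Detection]]:
        """Per-image detection lists for CHW float images in [0, 1]."""
        check_is_fitted(self, "model_")
        if isinstance(X, np.ndarray) and X.ndim == 3:
            X = [X]
        return predict(self.model_, list(X), self.conf_threshold, self.nms_iou)

    def evaluate(self, X, split: str = "val") -> EvalResult:
        """Full evaluation on a manifest split."""
        check_is_fitted(self, "model_")
        samples = load_split(self._manifest(X), split)
        dets = self.predict([s["image"] for s in samples])
        gt = [{"boxes": s["boxes"], "classes": s["classes"]} for s in samples]
        return evaluate_map(dets, gt, self.num_classes)

    def score(self, X, y=None) -> float:
        """mAP50 on the manifest's val split (sklearn scoring contract)."""
        return self.evaluate(X).map50
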