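"""Training harness: anchors, the assignment rule against a brute-force
oracle, NMS against an O(n^2) reference, decoding, and loop mechanics."""

import numpy as np
import pytest

from hadet.architecture import REG_MAX
from hadet.losses import Box, iou
from hadet.train_eval import (
    SCALE_RANGES,
    Detection,
    TrainConfig,
    assign_targets,
    build_model,
    compute_loss,
    load_checkpoint,
    make_anchors,
    nms,
    predict,
    save_checkpoint,
    train,
    TrainResult,
)
from hadet.nn import Tensor


def brute_force_assign(points, strides, boxes, classes):
    """Exhaustive enumeration of the assignment rule."""
    out = {}
    for a, ((px, py), s) in enumerate(zip(points, strides)):
        best, best_area = None, np.inf
        for g, (x1, y1, x2, y2) in enumerate(boxes):
            lo, hi = SCALE_RANGES[int(s)]
            long_side = max(x2 - x1, y2 - y1)
            if not (x1 <= px < x2 and y1 <= py < y2):
                continue
            if not (lo < long_side <= hi):
                continue
            area = (x2 - x1) * (y2 - y1)
            if area < best_area:
                best, best_area = g, area
        if best is not None:
            out[a] = best
    return out


def brute_force_nms(boxes, scores, thr):
    """O(n^2) reference suppressor."""
    alive = list(range(len(boxes)))
    kept = []
    while alive:
        i = max(alive, key=lambda k: scores[k])
        kept.append(i)
        alive = [
            k for k in alive
            if k != i and iou(Box.from_corners(*boxes[i]), Box.from_corners(*boxes[k])) <= thr
        ]
    return kept


class TestAnchors:
    def test_total_at_640(self):
        points, strides = make_anchors(640)
        assert len(points) == 8400
        assert {int(s) for s in strides} == {8, 16, 32}

    def test_points_are_cell_centers(self):
        points, strides = make_anchors(64)
        first_stride8 = points[0]
        np.testing.assert_allclose(first_stride8, [4.0, 4.0])


class TestAssignment:
    def test_empty_ground_truth(self):
        points, strides = make_anchors(64)
        a, g = assign_targets(points, strides, np.zeros((0, 4)), np.zeros(0))
        assert len(a) == len(g) == 0

    def test_single_cell_box_at_stride8(self):
        points, strides = make_anchors(64)
        # covers exactly the first stride-8 cell center (4, 4)
        boxes = np.array([[1.0, 1.0, 7.0, 7.0]])
        a, g = assign_targets(points, strides, boxes, np.array([0]))
        assert list(a) == [0] and list(g) == [0]

    def test_nested_boxes_take_smaller_area(self):
        points, strides = make_anchors(64)
        boxes = np.array([[0.0, 0.0, 40.0, 40.0], [10.0, 10.0, 30.0, 30.0]])
        a, g = assign_targets(points, strides, boxes, np.array([0, 1]))
        inner = points[a][:, 0]
        for ai, gi in zip(a, g):
            px, py = points[ai]
            if 10 <= px < 30 and 10 <= py < 30:
                assert gi == 1
            else:
                assert gi == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        points, strides = make_anchors(96)
        boxes = []
        for _ in range(r.integers(1, 6)):
            x1, y1 = r.uniform(0, 60, 2)
            w, h = r.uniform(5, 90, 2)
            boxes.append([x1, y1, min(96, x1 + w), min(96, y1 + h)])
        boxes = np.array(boxes)
        classes = r.integers(0, 4, len(boxes))
        a, g = assign_targets(points, strides, boxes, classes)
        assert dict(zip(a.tolist(), g.tolist())) == brute_force_assign(
            points, strides, boxes, classes
        )


class TestNMS:
    def test_identical_boxes_keep_one(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], dtype=float)
        keep = nms(boxes, np.array([0.9, 0.8]), 0.7)
        assert list(keep) == [0]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_on_50_boxes(self, seed):
        r = np.random.default_rng(seed)
        xy = r.uniform(0, 80, (50, 2))
        wh = r.uniform(5, 40, (50, 2))
        boxes = np.concatenate([xy, xy + wh], axis=1)
        scores = r.uniform(0.05, 1.0, 50)
        assert list(nms(boxes, scores, 0.5)) == brute_force_nms(boxes, scores, 0.5)


class TestLossComputation:
    def _fake_outputs(self, rng, bsz, imgsz, nc=4):
        outs = []
        for s in (8, 16, 32):
            n = imgsz // s
            box = Tensor(rng.normal(size=(bsz, 4 * REG_MAX, n, n)).astype(np.float32),
                         requires_grad=True)
            cls = Tensor(rng.normal(size=(bsz, nc, n, n)).astype(np.float32),
                         requires_grad=True)
            outs.append((box, cls))
        return outs

    def test_no_ground_truth_gives_cls_only(self, rng):
        cfg = TrainConfig(imgsz=64)
        points, strides = make_anchors(64)
        outs = self._fake_outputs(rng, 2, 64)
        total, parts = compute_loss(
            outs, [{"boxes": np.zeros((0, 4)), "classes": np.zeros(0)}] * 2,
            cfg, points, strides)
        assert parts["n_pos"] == 0
        assert parts["box"] == parts["dfl"] == 0.0
        assert parts["cls"] > 0

    def test_loss_is_differentiable_and_finite(self, rng):
        cfg = TrainConfig(imgsz=64)
        points, strides = make_anchors(64)
        outs = self._fake_outputs(rng, 1, 64)
        tgt = [{"boxes": np.array([[8.0, 8.0, 40.0, 40.0]]), "classes": np.array([2])}]
        total, parts = compute_loss(outs, tgt, cfg, points, strides)
        assert np.isfinite(parts["total"])
        total.backward()
        for box, cls in outs:
            assert box.grad is not None and np.isfinite(box.grad).all()
            assert cls.grad is not None and np.isfinite(cls.grad).all()

    def test_hkciou_and_ciou_differ(self, rng):
        points, strides = make_anchors(64)
        outs = self._fake_outputs(rng, 1, 64)
        tgt = [{"boxes": np.array([[8.0, 8.0, 40.0, 40.0]]), "classes": np.array([1])}]
        _, a = compute_loss(outs, tgt, TrainConfig(imgsz=64, box_loss="ciou"),
                            points, strides)
        _, b = compute_loss(outs, tgt, TrainConfig(imgsz=64, box_loss="hkciou"),
                            points, strides)
        assert a["box"] != b["box"]
        assert a["cls"] == pytest.approx(b["cls"])


class TestTrainingLoop:
    def test_zero_lr_leaves_parameters_unchanged(self, tiny_dataset):
        cfg = TrainConfig(epochs=1, batch_size=4, imgsz=96, seed=3,
                          model="baseline", lr0=0.0, warmup_epochs=0,
                          hflip=False, value_jitter=0.0)
        model = build_model("baseline", 4, seed=3, input_size=96)
        before = {k: v.copy() for k, v in model.state_arrays().items()
                  if not k.endswith("running_mean") and not k.endswith("running_var")}
        result = train(tiny_dataset, cfg, model=model)
        after = result.model.state_arrays()
        for k, v in before.items():
            np.testing.assert_array_equal(v, after[k], err_msg=k)

    def test_history_and_determinism(self, tiny_dataset):
        cfg = TrainConfig(epochs=2, batch_size=4, imgsz=96, seed=11, model="baseline")
        r1 = train(tiny_dataset, cfg)
        r2 = train(tiny_dataset, cfg)
        assert len(r1.history) == 2
        assert r1.history == r2.history

    def test_checkpoint_roundtrip(self, tiny_dataset, tmp_path):
        cfg = TrainConfig(epochs=1, batch_size=4, imgsz=96, seed=2, model="baseline")
        result = train(tiny_dataset, cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(result, path)
        loaded = load_checkpoint(path)
        a = result.model.state_arrays()
        b = loaded.model.state_arrays()
        assert a.keys() == b.keys()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
        assert loaded.history == result.history


class TestPredict:
    def test_conf_threshold_one_gives_nothing(self, rng):
        model = build_model("baseline", 4, seed=0, input_size=64)
        img = rng.uniform(0, 1, (3, 64, 64)).astype(np.float32)
        (dets,) = predict(model, img, conf_threshold=1.0)
        assert dets == []

    def test_detections_are_valid(self, rng):
        model = build_model("ha", 4, seed=0, input_size=64)
        img = rng.uniform(0, 1, (3, 64, 64)).astype(np.float32)
        (dets,) = predict(model, img, conf_threshold=0.05)
        for d in dets:
            assert isinstance(d, Detection)
            assert 0.05 <= d.confidence <= 1.0
            x1, y1, x2, y2 = d.xyxy
            assert 0 <= x1 < x2 <= 64 and 0 <= y1 < y2 <= 64
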