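"""Loss suite: closed-form cases, geometric invariances, the hook identity,
analytic-vs-numeric gradients, and the rasterization IoU oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hadet.exceptions import DomainError, InvalidBoxError, InvalidConfigError
from hadet.losses import (
    Box,
    HookParams,
    LossWeights,
    box_regression_loss_t,
    ciou,
    dfl_loss,
    hkciou_loss,
    hook,
    iou,
    iou_matrix,
    pairwise_ciou_t,
    total_loss,
)
from hadet.nn import Tensor


def raster_iou(p: Box, t: Box, cells_per_unit: int = 256) -> float:
    """Pixel-counting IoU oracle on a fine grid covering both boxes."""
    x1 = min(p.corners[0], t.corners[0])
    y1 = min(p.corners[1], t.corners[1])
    x2 = max(p.corners[2], t.corners[2])
    y2 = max(p.corners[3], t.corners[3])
    nx = max(1, int(round((x2 - x1) * cells_per_unit)))
    ny = max(1, int(round((y2 - y1) * cells_per_unit)))
    xs = x1 + (np.arange(nx) + 0.5) / cells_per_unit
    ys = y1 + (np.arange(ny) + 0.5) / cells_per_unit
    gx, gy = np.meshgrid(xs, ys)

    def mask(b: Box):
        bx1, by1, bx2, by2 = b.corners
        return (gx >= bx1) & (gx < bx2) & (gy >= by1) & (gy < by2)

    mp, mt = mask(p), mask(t)
    union = (mp | mt).sum()
    return float((mp & mt).sum() / union) if union else 0.0


def quantized_box(rng, step=1 / 256) -> Box:
    x1, y1 = rng.integers(0, 512, 2) * step
    w, h = rng.integers(8, 512, 2) * step
    return Box.from_corners(x1, y1, x1 + w, y1 + h)


class TestIoU:
    def test_identical_is_one(self):
        b = Box(1, 2, 3, 4)
        assert iou(b, b) == 1.0

    def test_disjoint_is_zero(self):
        assert iou(Box(0, 0, 1, 1), Box(5, 5, 1, 1)) == 0.0

    def test_worked_example_vs_raster_oracle(self):
        p = Box.from_corners(0, 0, 2, 2)
        t = Box.from_corners(1, 1, 3, 3)
        assert iou(p, t) == pytest.approx(1 / 7, abs=1e-12)
        assert raster_iou(p, t) == pytest.approx(1 / 7, abs=1e-3)

    def test_symmetry_translation_scale_invariance(self, rng):
        for _ in range(50):
            a = rng.uniform(0.5, 4, 4)
            b = rng.uniform(0.5, 4, 4)
            p, t = Box(*a), Box(*b)
            assert iou(p, t) == pytest.approx(iou(t, p), abs=1e-12)
            dx, dy = rng.uniform(-5, 5, 2)
            shifted = iou(Box(a[0] + dx, a[1] + dy, a[2], a[3]),
                          Box(b[0] + dx, b[1] + dy, b[2], b[3]))
            assert shifted == pytest.approx(iou(p, t), abs=1e-12)
            s = rng.uniform(0.5, 3)
            scaled = iou(Box(*(a * s)), Box(*(b * s)))
            assert scaled == pytest.approx(iou(p, t), rel=1e-9)

    def test_degenerate_box_rejected(self):
        with pytest.raises(InvalidBoxError):
            Box(0, 0, 0.0, 1.0)

    def test_matrix_agrees_with_scalar(self, rng):
        boxes_a = [quantized_box(rng) for _ in range(8)]
        boxes_b = [quantized_box(rng) for _ in range(5)]
        mat = iou_matrix(np.array([a.corners for a in boxes_a]),
                         np.array([b.corners for b in boxes_b]))
        for i, a in enumerate(boxes_a):
            for j, b in enumerate(boxes_b):
                assert mat[i, j] == pytest.approx(iou(a, b), abs=1e-12)


class TestCIoU:
    def test_identical_boxes(self):
        b = Box(0, 0, 2, 3)
        r = ciou(b, b)
        assert (r.iou, r.center_term, r.aspect_v, r.ciou) == (1.0, 0.0, 0.0, 1.0)

    def test_same_center_same_aspect_scaled(self):
        r = ciou(Box(1, 1, 2, 1), Box(1, 1, 4, 2))
        assert r.aspect_v == pytest.approx(0.0, abs=1e-15)
        assert r.ciou == pytest.approx(r.iou, abs=1e-12)

    def test_independent_scalar_transcription(self):
        # second implementation straight from the printed equations
        p, t = Box(0, 0, 2, 1), Box(1, 1, 1, 2)
        i = iou(p, t)
        rho2 = (0 - 1) ** 2 + (0 - 1) ** 2
        cw = max(1, 1.5) - min(-1, 0.5)
        chh = max(0.5, 2) - min(-0.5, 0)
        c2 = cw**2 + chh**2
        v = 4 / math.pi**2 * (math.atan(1 / 2) - math.atan(2 / 1)) ** 2
        alpha = v / (1 - i + v)
        expected = i - rho2 / c2 - alpha * v
        r = ciou(p, t)
        assert r.ciou == pytest.approx(expected, abs=1e-12)
        assert r.center_term == pytest.approx(rho2 / c2, abs=1e-12)
        assert r.aspect_v == pytest.approx(v, abs=1e-12)

    def test_ciou_never_exceeds_iou(self, rng):
        for _ in range(100):
            p, t = Box(*rng.uniform(0.5, 4, 4)), Box(*rng.uniform(0.5, 4, 4))
            r = ciou(p, t)
            assert r.ciou <= r.iou + 1e-12
            assert -2.0 < r.ciou <= 1.0


class TestHook:
    def test_minimum_at_one_for_default_params(self):
        assert hook(1.0) == 1.0
        xs = np.linspace(1e-3, 10, 20001)
        vals = [hook(float(x)) for x in xs]
        assert xs[int(np.argmin(vals))] == pytest.approx(1.0, abs=1e-3)

    def test_direct_arithmetic(self):
        assert hook(2.0) == pytest.approx(1.25, abs=1e-15)

    def test_reciprocal_symmetry_when_a_equals_b(self):
        for x in np.linspace(0.1, 10, 25):
            assert hook(float(x)) == pytest.approx(hook(float(1 / x)), rel=1e-12)

    def test_minimizer_formula(self):
        hp = HookParams(a=2.0, b=0.5)
        assert hp.minimizer == 0.5
        xs = np.linspace(1e-3, 5, 50001)
        vals = hp.a * xs + hp.b / xs
        assert xs[int(np.argmin(vals))] == pytest.approx(0.5, abs=1e-3)

    def test_domain_and_config_errors(self):
        with pytest.raises(DomainError):
            hook(0.0)
        with pytest.raises(DomainError):
            hook(-1.0)
        with pytest.raises(InvalidConfigError):
            HookParams(a=0.0)


class TestHKCIoU:
    def test_identical_boxes_value_is_b(self):
        b = Box(0, 0, 2, 2)
        assert hkciou_loss(b, b) == pytest.approx(0.5, abs=1e-12)

    def test_hook_identity_on_loss_values(self):
        # hkciou(L) = hook(L) * L = a*L^2 + b, checked against independent hook
        for L in (0.25, 0.5, 1.0, 1.5, 2.0):
            direct = 0.5 * L * L + 0.5
            assert direct == pytest.approx(hook(L) * L, abs=1e-12)
        assert 0.5 * 1**2 + 0.5 == 1.0           # L=1: the hook minimum
        assert 0.5 * 2**2 + 0.5 == 2.5           # L=2 amplified beyond plain 2
        assert 0.5 * 0.5**2 + 0.5 == 0.625       # L=0.5 damped

    def test_gradient_ordering(self):
        # d(hkciou)/dL = 2aL: amplified for poor boxes, damped for good ones
        a = 0.5
        assert 2 * a * 2.0 > 1.0 > 2 * a * 0.5

    def test_metric_mode(self):
        b = Box(0, 0, 2, 2)
        assert hkciou_loss(b, b, HookParams(mode="metric")) == pytest.approx(
            0.5 * 1.0**2 + 0.5
        )

    def test_batched_matches_scalar(self, rng):
        preds, tgts = [], []
        for _ in range(20):
            preds.append(Box(*rng.uniform(0.5, 4, 4)))
            tgts.append(Box(*rng.uniform(0.5, 4, 4)))
        P = Tensor(np.array([p.corners for p in preds], dtype=np.float64))
        T = Tensor(np.array([t.corners for t in tgts]))
        for kind in ("ciou", "hkciou"):
            batched = box_regression_loss_t(P, T, kind).numpy()
            for k, (p, t) in enumerate(zip(preds, tgts)):
                expected = (1 - ciou(p, t).ciou) if kind == "ciou" else hkciou_loss(p, t)
                assert batched[k] == pytest.approx(expected, abs=1e-6)


class TestDFL:
    def test_point_mass_on_integer_target(self):
        assert dfl_loss(np.eye(16)[3], 3.0) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_distribution(self):
        assert dfl_loss(np.ones(16) / 16, 9.4) == pytest.approx(math.log(16), abs=1e-9)

    def test_two_bin_mixture(self):
        p = np.zeros(16)
        p[5], p[6] = 0.75, 0.25
        expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert dfl_loss(p, 5.25) == pytest.approx(expected, abs=1e-9)

    def test_target_range_enforced(self):
        with pytest.raises(DomainError):
            dfl_loss(np.ones(16) / 16, 15.5)
        with pytest.raises(DomainError):
            dfl_loss(np.ones(16) / 16, -0.1)

    def test_top_bin_target_supervises_last_pair(self):
        p = np.zeros(16)
        p[15] = 1.0
        assert dfl_loss(p, 15.0) == pytest.approx(0.0, abs=1e-9)


class TestTotalLoss:
    @pytest.mark.parametrize(
        "terms,weights,expected",
        [
            ((0.0, 0.0, 0.0), LossWeights(), 0.0),
            ((0.2, 0.3, 0.5), LossWeights(1, 1, 1), 1.0),
            ((1.0, 1.0, 1.0), LossWeights(), 9.5),
        ],
    )
    def test_weighted_sums(self, terms, weights, expected):
        r = total_loss(*terms, weights)
        assert r.total == pytest.approx(expected, abs=1e-12)
        assert (r.l_box, r.l_obj, r.l_cls) == terms

    def test_negative_component_rejected(self):
        with pytest.raises(InvalidConfigError):
            total_loss(-0.1, 0, 0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(InvalidConfigError):
            LossWeights(0, 0, 0)


class TestGradients:
    def test_finite_difference_on_100_box_pairs(self, rng):
        """Analytic gradients of the CIoU/HKCIoU losses vs central differences."""
        eps = 1e-6
        for _ in range(100):
            p = np.sort(rng.uniform(0.2, 4.0, (2, 2)), axis=1)
            pred = np.array([p[0, 0], p[1, 0], p[0, 1] + 0.2, p[1, 1] + 0.2])
            t = np.sort(rng.uniform(0.2, 4.0, (2, 2)), axis=1)
            tgt = np.array([[t[0, 0], t[1, 0], t[0, 1] + 0.2, t[1, 1] + 0.2]])
            kind = "ciou" if rng.random() < 0.5 else "hkciou"

            x = Tensor(pred.reshape(1, 4).astype(np.float64), requires_grad=True)
            box_regression_loss_t(x, Tensor(tgt), kind).sum().backward()
            grad = x.grad.ravel()
            for k in range(4):
                up, dn = pred.copy(), pred.copy()
                up[k] += eps
                dn[k] -= eps
                fu = float(box_regression_loss_t(Tensor(up.reshape(1, 4)), Tensor(tgt), kind).numpy()[0])
                fd = float(box_regression_loss_t(Tensor(dn.reshape(1, 4)), Tensor(tgt), kind).numpy()[0])
                assert grad[k] == pytest.approx((fu - fd) / (2 * eps), abs=1e-4, rel=1e-4)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_raster_oracle_equivalence(self, seed):
        r = np.random.default_rng(seed)
        p, t = quantized_box(r), quantized_box(r)
        assert iou(p, t) == pytest.approx(raster_iou(p, t), abs=1e-3)
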