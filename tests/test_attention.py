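"""Attention operators: worked scalar cases, convolution oracle, and the
shape/permutation/gate invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hadet.attention import (
    DualChannelConfig,
    DualChannelModule,
    EnergyGateParams,
    Shuffle3DModule,
    ShuffleSpec,
    SpatialAttentionConfig,
    channel_shuffle,
    dual_channel,
    energy_gate,
    shuffle3d,
    shuffle_permutation,
    spatial_attention,
)
from hadet.exceptions import DegenerateInputError, InvalidConfigError, InvalidSpecError
from hadet.nn import Tensor


def naive_conv2d(x, w, bias, padding):
    """Nested-loop sliding-window convolution oracle."""
    b, cin, h, wd = x.shape
    cout, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    out = np.zeros((b, cout, h, wd))
    for bi in range(b):
        for co in range(cout):
            for i in range(h):
                for j in range(wd):
                    acc = bias[co]
                    for ci in range(cin):
                        for u in range(kh):
                            for v in range(kw):
                                acc += w[co, ci, u, v] * xp[bi, ci, i + u, j + v]
                    out[bi, co, i, j] = acc
    return out


class TestChannelShuffle:
    @pytest.mark.parametrize(
        "channels,groups,expected",
        [(4, 2, [0, 2, 1, 3]), (6, 3, [0, 2, 4, 1, 3, 5])],
    )
    def test_group_interleave_order(self, channels, groups, expected):
        # brute-force index-permutation oracle: channel c of group g lands at
        # position (c mod per_group) * groups + g
        per = channels // groups
        oracle = [0] * channels
        for src in range(channels):
            g, within = divmod(src, per)
            oracle[within * groups + g] = src
        assert oracle == expected
        assert shuffle_permutation(channels, ShuffleSpec(groups)).tolist() == expected

    def test_groups_one_is_identity(self, rng):
        x = rng.normal(size=(2, 5, 3, 3))
        assert np.array_equal(channel_shuffle(x, ShuffleSpec(1)), x)

    def test_indivisible_groups_rejected(self, rng):
        with pytest.raises(InvalidSpecError):
            channel_shuffle(rng.normal(size=(1, 6, 2, 2)), ShuffleSpec(4))

    @given(st.integers(1, 4), st.integers(1, 4), st.data())
    @settings(max_examples=25, deadline=None)
    def test_permutation_conserves_multiset(self, groups, per_group, data):
        channels = groups * per_group
        seed = data.draw(st.integers(0, 2**31 - 1))
        x = np.random.default_rng(seed).normal(size=(2, channels, 3, 4))
        mode = data.draw(st.sampled_from(["group", "random"]))
        y = channel_shuffle(x, ShuffleSpec(groups, mode=mode, seed=seed))
        assert np.array_equal(np.sort(y, axis=1), np.sort(x, axis=1))

    def test_random_mode_deterministic_per_seed(self, rng):
        x = rng.normal(size=(1, 8, 2, 2))
        a = channel_shuffle(x, ShuffleSpec(4, "random", seed=3))
        b = channel_shuffle(x, ShuffleSpec(4, "random", seed=3))
        c = channel_shuffle(x, ShuffleSpec(4, "random", seed=4))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestEnergyGate:
    def test_zero_input_stays_zero(self):
        assert np.all(energy_gate(np.zeros((1, 2, 3, 3))) == 0)

    def test_constant_slice_worked_value(self):
        # independent scalar evaluation of the printed equations:
        # e = 4/3, u = (1-4/3)^2 / (4*(4/3+1e-4)) + 0.5, out = sigmoid(u)*1
        out = energy_gate(np.ones((1, 1, 2, 2)))
        assert out == pytest.approx(0.6273422416019442 * np.ones((1, 1, 2, 2)), abs=1e-9)

    def test_shape_preserved(self, rng):
        x = rng.normal(size=(2, 8, 5, 7))
        assert energy_gate(x).shape == x.shape

    def test_gate_strictly_contracts(self, rng):
        x = rng.normal(size=(2, 3, 6, 6)) + 2.0
        y = energy_gate(x)
        nz = x != 0
        assert np.all(np.abs(y[nz]) < np.abs(x[nz]))

    def test_single_pixel_slice_rejected(self):
        with pytest.raises(DegenerateInputError):
            energy_gate(np.ones((1, 1, 1, 1)))

    def test_non_finite_rejected(self):
        x = np.ones((1, 1, 2, 2))
        x[0, 0, 0, 0] = np.nan
        with pytest.raises(DegenerateInputError):
            energy_gate(x)

    def test_variance_mode_differs(self, rng):
        x = rng.normal(size=(1, 2, 4, 4)) + 3.0
        a = energy_gate(x, EnergyGateParams())
        b = energy_gate(x, EnergyGateParams(variance=True))
        assert not np.allclose(a, b)

    def test_per_slice_independence(self, rng):
        x = rng.normal(size=(2, 3, 4, 4))
        full = energy_gate(x)
        solo = energy_gate(x[1:2, 2:3])
        assert np.allclose(full[1:2, 2:3], solo)


class TestShuffle3D:
    def test_groups_one_equals_energy_gate(self, rng):
        x = rng.normal(size=(1, 6, 4, 4))
        assert np.allclose(shuffle3d(x, ShuffleSpec(1)), energy_gate(x))

    def test_zero_input_zero_output(self):
        assert np.all(shuffle3d(np.zeros((1, 4, 3, 3)), ShuffleSpec(2)) == 0)

    def test_composition_of_component_oracles(self, rng):
        # constant channels: compose the two component oracles by hand
        consts = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.broadcast_to(consts[None, :, None, None], (1, 4, 3, 3)).copy()
        spec = ShuffleSpec(2)
        expected = energy_gate(channel_shuffle(x, spec))
        assert np.allclose(shuffle3d(x, spec), expected)

    def test_parameter_free(self):
        assert Shuffle3DModule(16).num_params() == 0

    def test_module_matches_functional(self, rng):
        x = rng.normal(size=(2, 8, 5, 5)).astype(np.float32)
        spec = ShuffleSpec(4)
        mod = Shuffle3DModule(8, spec)
        assert np.allclose(mod(Tensor(x)).numpy(), shuffle3d(x, spec), atol=1e-6)


class TestSpatialAttention:
    def test_zero_weights_halve_input(self, rng):
        x = rng.normal(size=(2, 3, 5, 5))
        assert np.allclose(spatial_attention(x, SpatialAttentionConfig()), 0.5 * x)

    def test_channel_constant_descriptors_coincide(self, rng):
        # x constant over channels: max and mean descriptors both equal the map
        base = rng.normal(size=(1, 1, 6, 6))
        x = np.repeat(base, 4, axis=1)
        w = np.zeros((1, 2, 7, 7))
        w[0, 0, 3, 3] = 1.0  # pick out d_max
        a = spatial_attention(x, SpatialAttentionConfig(weights=w))
        w2 = np.zeros((1, 2, 7, 7))
        w2[0, 1, 3, 3] = 1.0  # pick out d_mean
        b = spatial_attention(x, SpatialAttentionConfig(weights=w2))
        assert np.allclose(a, b, atol=1e-6)

    def test_matches_nested_loop_conv_oracle(self, rng):
        x = rng.normal(size=(1, 3, 8, 8))
        cfg = SpatialAttentionConfig.initialize(rng)
        d_max = x.max(axis=1, keepdims=True)
        d_mean = x.mean(axis=1, keepdims=True)
        desc = np.concatenate([d_max, d_mean], axis=1)
        conv = naive_conv2d(desc, cfg.weights, np.array([cfg.bias]), 3)
        expected = x / (1.0 + np.exp(-conv))
        assert np.allclose(spatial_attention(x, cfg), expected, atol=1e-8)

    def test_gate_bound(self, rng):
        x = rng.normal(size=(2, 4, 6, 6))
        cfg = SpatialAttentionConfig.initialize(rng)
        assert np.all(np.abs(spatial_attention(x, cfg)) <= np.abs(x) + 1e-12)

    def test_bad_weight_shape_rejected(self):
        with pytest.raises(InvalidConfigError):
            SpatialAttentionConfig(weights=np.zeros((1, 2, 5, 5)))

    def test_shape_must_be_preserved(self):
        with pytest.raises(InvalidConfigError):
            SpatialAttentionConfig(kernel=7, padding=1)


class TestDualChannel:
    def test_zero_input_zero_output(self, rng):
        cfg = DualChannelConfig.initialize(4, rng)
        assert np.all(dual_channel(np.zeros((1, 4, 6, 6)), cfg) == 0)

    def test_shape_preserved_default(self, rng):
        x = rng.normal(size=(2, 64, 20, 20))
        cfg = DualChannelConfig.initialize(64, rng)
        assert dual_channel(x, cfg).shape == x.shape

    def test_channel_mismatch_rejected(self, rng):
        cfg = DualChannelConfig.initialize(8, rng)
        with pytest.raises(InvalidConfigError):
            dual_channel(rng.normal(size=(1, 4, 5, 5)), cfg)

    def test_param_count_closed_form(self):
        # closed-form arithmetic oracle for the published example shape
        cfg = DualChannelConfig(channels_in=128, branch_channels=64)
        expected = (128 * 64 * 9 + 64) + (128 * 64 * 25 + 64) \
            + (128 * 128 * 1 + 128) + (2 * 1 * 49 + 1)
        assert cfg.num_params == expected
        mod = DualChannelModule(128, branch_channels=64)
        assert mod.num_params() == expected

    def test_module_matches_functional(self, rng):
        x = rng.normal(size=(1, 8, 6, 6)).astype(np.float32)
        mod = DualChannelModule(8, rng=np.random.default_rng(3))
        cfg = DualChannelConfig.initialize(8, np.random.default_rng(3))
        assert np.allclose(mod(Tensor(x)).numpy(), dual_channel(x, cfg), atol=1e-5)


class TestSharedInvariants:
    @pytest.mark.parametrize("seed", range(4))
    def test_shape_preservation_randomized(self, seed):
        r = np.random.default_rng(seed)
        groups = int(r.integers(1, 4))
        c = groups * int(r.integers(1, 5))
        shape = (int(r.integers(1, 3)), c, int(r.integers(2, 9)), int(r.integers(2, 9)))
        x = r.normal(size=shape)
        spec = ShuffleSpec(groups)
        assert shuffle3d(x, spec).shape == shape
        cfg = SpatialAttentionConfig.initialize(r)
        assert spatial_attention(x, cfg).shape == shape
        dc = DualChannelConfig.initialize(c, r)
        assert dual_channel(x, dc).shape == shape

    def test_determinism_bit_identical(self, rng):
        x = rng.normal(size=(1, 8, 5, 5))
        spec = ShuffleSpec(4, "random", seed=11)
        assert np.array_equal(shuffle3d(x, spec), shuffle3d(x, spec))
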