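"""Attention operators: Shuffle3D, Spatial attention, Dual-channel attention.

All three are shape-preserving transforms of a feature map (a real array
indexed ``batch x channel x height x width``).

* **Shuffle3D** is parameter-free: a channel rearrangement (group interleave
  or a seeded random permutation) followed by a spatial-inhibition energy
  gate.  The gate scores each position by its squared deviation from the
  channel-slice mean, normalized by the slice statistic, and multiplies the
  map by the sigmoid of that score — positions that stand out from their
  surround are kept, the rest are suppressed.
* **Spatial attention** pools the channel axis with max and mean, stacks the
  two descriptors, convolves them to a single-channel map (7x7 by default)
  and gates the input with its sigmoid.
* **Dual-channel attention** runs two parallel convolutions with different
  kernel sizes over the input, concatenates and fuses them with a 1x1
  convolution, computes a spatial-attention map from the fused tensor, and
  multiplies the *input* by that sigmoid map.

The functional entry points (:func:`channel_shuffle`, :func:`energy_gate`,
:func:`shuffle3d`, :func:`spatial_attention`, :func:`dual_channel`) take and
return plain numpy arrays; the ``*Module`` classes wrap the same math for use
inside the trainable network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .exceptions import DegenerateInputError, InvalidConfigError, InvalidSpecError
from .nn import Tensor

__all__ = [
    "EnergyGateParams",
    "ShuffleSpec",
    "SpatialAttentionConfig",
    "DualChannelConfig",
    "channel_shuffle",
    "energy_gate",
    "shuffle3d",
    "spatial_attention",
    "dual_channel",
    "shuffle_permutation",
    "Shuffle3DModule",
    "SpatialAttentionModule",
    "DualChannelModule",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergyGateParams:
    """Regulators of the spatial-inhibition energy.

    ``alpha`` stabilizes the normalizing denominator, ``beta`` shifts the
    energy before the sigmoid.  ``variance=True`` swaps the as-written mean
    statistic in the denominator for the slice variance (the form the cited
    parameter-free attention family normally uses); the default keeps the
    printed formulation.
    """

    alpha: float = 1e-4
    beta: float = 0.5
    variance: bool = False

    def __post_init__(self):
        if self.alpha <= 0:
            raise InvalidConfigError(f"alpha must be > 0, got {self.alpha}")


@dataclass(frozen=True)
class ShuffleSpec:
    """Channel rearrangement: deterministic group interleave or a seeded
    uniform permutation."""

    groups: int = 4
    mode: str = "group"
    seed: int = 0

    def __post_init__(self):
        if self.groups < 1:
            raise InvalidSpecError(f"groups must be >= 1, got {self.groups}")
        if self.mode not in ("group", "random"):
            raise InvalidSpecError(f"mode must be 'group' or 'random', got {self.mode!r}")


def shuffle_permutation(channels: int, spec: ShuffleSpec) -> np.ndarray:
    """The channel permutation a :class:`ShuffleSpec` induces."""
    if channels % spec.groups:
        raise InvalidSpecError(
            f"groups={spec.groups} does not divide channel count {channels}"
        )
    if spec.mode == "group":
        return (
            np.arange(channels)
            .reshape(spec.groups, channels // spec.groups)
            .T.reshape(-1)
        )
    return np.random.default_rng(spec.seed).permutation(channels)


@dataclass
class SpatialAttentionConfig:
    """7x7 (by default) convolution over the stacked max/mean descriptors."""

    kernel: int = 7
    stride: int = 1
    padding: int | None = None
    weights: np.ndarray | None = None  # (1, 2, kernel, kernel)
    bias: float = 0.0

    def __post_init__(self):
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise InvalidConfigError(f"kernel must be odd positive, got {self.kernel}")
        if self.padding is None:
            self.padding = (self.kernel - 1) // 2
        if self.padding != (self.kernel - 1) // 2 or self.stride != 1:
            raise InvalidConfigError(
                "spatial attention must preserve the spatial shape: "
                "stride 1 and padding (kernel-1)/2"
            )
        if self.weights is None:
            self.weights = np.zeros((1, 2, self.kernel, self.kernel))
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (1, 2, self.kernel, self.kernel):
            raise InvalidConfigError(
                f"weights shape {self.weights.shape} != (1, 2, {self.kernel}, {self.kernel})"
            )

    @classmethod
    def initialize(cls, rng: np.random.Generator, kernel: int = 7) -> "SpatialAttentionConfig":
        fan_in = 2 * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (1, 2, kernel, kernel))
        return cls(kernel=kernel, weights=w, bias=0.0)


@dataclass
class DualChannelConfig:
    """Two parallel branch convolutions, a 1x1 fuse back to the input width,
    and the spatial-attention gate computed from the fused tensor.

    ``branch_channels`` defaults to ``channels_in // 8``; the published
    variant statistics pin this reduction (see the methods note).
    """

    channels_in: int
    branch_kernels: tuple[int, int] = (3, 5)
    branch_channels: int | None = None
    fuse_kernel: int = 1
    w1: np.ndarray | None = None
    b1: np.ndarray | None = None
    w2: np.ndarray | None = None
    b2: np.ndarray | None = None
    w_fuse: np.ndarray | None = None
    b_fuse: np.ndarray | None = None
    spatial: SpatialAttentionConfig = field(default_factory=SpatialAttentionConfig)

    def __post_init__(self):
        k1, k2 = self.branch_kernels
        if k1 == k2 or k1 % 2 == 0 or k2 % 2 == 0:
            raise InvalidConfigError(
                f"branch kernels must be distinct odd integers, got {self.branch_kernels}"
            )
        if self.branch_channels is None:
            self.branch_channels = max(1, self.channels_in // 8)
        bc, c = self.branch_channels, self.channels_in
        shapes = {
            "w1": (bc, c, k1, k1),
            "b1": (bc,),
            "w2": (bc, c, k2, k2),
            "b2": (bc,),
            "w_fuse": (c, 2 * bc, self.fuse_kernel, self.fuse_kernel),
            "b_fuse": (c,),
        }
        for name, shape in shapes.items():
            v = getattr(self, name)
            if v is None:
                v = np.zeros(shape)
            v = np.asarray(v, dtype=np.float64)
            if v.shape != shape:
                raise InvalidConfigError(f"{name} shape {v.shape} != {shape}")
            setattr(self, name, v)

    @classmethod
    def initialize(cls, channels_in: int, rng: np.random.Generator,
                   **kw) -> "DualChannelConfig":
        cfg = cls(channels_in=channels_in, **kw)
        for w in ("w1", "w2", "w_fuse"):
            arr = getattr(cfg, w)
            fan_in = arr.shape[1] * arr.shape[2] * arr.shape[3]
            setattr(cfg, w, rng.normal(0.0, np.sqrt(2.0 / fan_in), arr.shape))
        cfg.spatial = SpatialAttentionConfig.initialize(rng, cfg.spatial.kernel)
        return cfg

    @property
    def num_params(self) -> int:
        n = sum(getattr(self, a).size for a in ("w1", "b1", "w2", "b2", "w_fuse", "b_fuse"))
        return n + self.spatial.weights.size + 1


# ---------------------------------------------------------------------------
# core math on tensors (shared by functional API and network modules)
# ---------------------------------------------------------------------------


def _check_featuremap(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 4 or min(x.shape) < 1:
        raise DegenerateInputError(f"feature map must be 4-axis, got shape {x.shape}")
    if not np.isfinite(x).all():
        raise DegenerateInputError("feature map contains non-finite values")
    return x


def energy_gate_t(x: Tensor, p: EnergyGateParams) -> Tensor:
    """Spatial-inhibition gate applied independently per (batch, channel)."""
    h, w = x.shape[2], x.shape[3]
    if h * w < 2:
        raise DegenerateInputError(
            f"energy gate needs H*W >= 2 spatial positions, got {h}x{w}"
        )
    denom_n = h * w - 1
    e = x.sum(axis=(2, 3), keepdims=True) * (1.0 / denom_n)
    dev = x - e
    if p.variance:
        stat = (dev * dev).sum(axis=(2, 3), keepdims=True) * (1.0 / denom_n)
    else:
        stat = e
    u = (dev * dev) / ((stat + p.alpha) * 4.0) + p.beta
    return u.sigmoid() * x


def spatial_attention_map_t(x: Tensor, weight: Tensor, bias: Tensor,
                            padding: int) -> Tensor:
    d_max = x.max(axis=1, keepdims=True)
    d_mean = x.mean(axis=1, keepdims=True)
    desc = Tensor.concat([d_max, d_mean], axis=1)
    return desc.conv2d(weight, bias, stride=1, padding=padding).sigmoid()


def dual_channel_t(x: Tensor, w1, b1, w2, b2, wf, bf, sa_w, sa_b,
                   k1: int, k2: int, fuse_k: int, sa_pad: int) -> Tensor:
    br1 = x.conv2d(w1, b1, 1, (k1 - 1) // 2).silu()
    br2 = x.conv2d(w2, b2, 1, (k2 - 1) // 2).silu()
    fused = Tensor.concat([br1, br2], axis=1).conv2d(
        wf, bf, 1, (fuse_k - 1) // 2
    ).silu()
    gate = spatial_attention_map_t(fused, sa_w, sa_b, sa_pad)
    return x * gate


# ---------------------------------------------------------------------------
# functional API on numpy arrays
# ---------------------------------------------------------------------------


def channel_shuffle(x: np.ndarray, spec: ShuffleSpec) -> np.ndarray:
    """Permute channels; per spatial position the value multiset is kept."""
    x = _check_featuremap(x)
    perm = shuffle_permutation(x.shape[1], spec)
    return x[:, perm]


def energy_gate(x: np.ndarray, p: EnergyGateParams = EnergyGateParams()) -> np.ndarray:
    x = _check_featuremap(x)
    with nn.no_grad():
        return energy_gate_t(Tensor(x), p).numpy()


def shuffle3d(x: np.ndarray, spec: ShuffleSpec = ShuffleSpec(),
              p: EnergyGateParams = EnergyGateParams()) -> np.ndarray:
    """Channel shuffle followed by the energy gate; introduces no parameters."""
    return energy_gate(channel_shuffle(x, spec), p)


def spatial_attention(x: np.ndarray, cfg: SpatialAttentionConfig) -> np.ndarray:
    x = _check_featuremap(x)
    with nn.no_grad():
        gate = spatial_attention_map_t(
            Tensor(x), Tensor(cfg.weights), Tensor(np.array([cfg.bias])),
            cfg.padding,
        )
        return (Tensor(x) * gate).numpy()


def dual_channel(x: np.ndarray, cfg: DualChannelConfig,
                 sa: SpatialAttentionConfig | None = None) -> np.ndarray:
    x = _check_featuremap(x)
    if x.shape[1] != cfg.channels_in:
        raise InvalidConfigError(
            f"config expects {cfg.channels_in} channels, input has {x.shape[1]}"
        )
    sa = sa or cfg.spatial
    k1, k2 = cfg.branch_kernels
    with nn.no_grad():
        out = dual_channel_t(
            Tensor(x),
            Tensor(cfg.w1), Tensor(cfg.b1),
            Tensor(cfg.w2), Tensor(cfg.b2),
            Tensor(cfg.w_fuse), Tensor(cfg.b_fuse),
            Tensor(sa.weights), Tensor(np.array([sa.bias])),
            k1, k2, cfg.fuse_kernel, sa.padding,
        )
        return out.numpy()


# ---------------------------------------------------------------------------
# network modules
# ---------------------------------------------------------------------------


class Shuffle3DModule(nn.Module):
    """Parameter-free Shuffle3D block for in-network use.

    The permutation is drawn once at construction ("random" mode) or is the
    deterministic group interleave; it stays fixed across forward passes so
    downstream convolutions train against a stable channel order.
    """

    def __init__(self, channels: int, spec: ShuffleSpec = ShuffleSpec(),
                 params: EnergyGateParams = EnergyGateParams()):
        super().__init__()
        self.perm = shuffle_permutation(channels, spec)
        self.params = params

    def forward(self, x: Tensor) -> Tensor:
        return energy_gate_t(x[:, self.perm], self.params)


class SpatialAttentionModule(nn.Module):
    def __init__(self, kernel: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        cfg = SpatialAttentionConfig.initialize(rng, kernel)
        self.padding = cfg.padding
        self.weight = Tensor(cfg.weights.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.array([cfg.bias], dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x * spatial_attention_map_t(x, self.weight, self.bias, self.padding)


class DualChannelModule(nn.Module):
    def __init__(self, channels_in: int, rng: np.random.Generator | None = None,
                 branch_channels: int | None = None,
                 branch_kernels: tuple[int, int] = (3, 5), fuse_kernel: int = 1):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        cfg = DualChannelConfig.initialize(
            channels_in, rng, branch_channels=branch_channels,
            branch_kernels=branch_kernels, fuse_kernel=fuse_kernel,
        )
        self.cfg_shape = (channels_in, cfg.branch_channels, branch_kernels, fuse_kernel)
        as_param = lambda a: Tensor(a.astype(np.float32), requires_grad=True)
        self.w1, self.b1 = as_param(cfg.w1), as_param(cfg.b1)
        self.w2, self.b2 = as_param(cfg.w2), as_param(cfg.b2)
        self.w_fuse, self.b_fuse = as_param(cfg.w_fuse), as_param(cfg.b_fuse)
        self.sa_weight = as_param(cfg.spatial.weights)
        self.sa_bias = as_param(np.array([cfg.spatial.bias]))
        self.sa_padding = cfg.spatial.padding

    def forward(self, x: Tensor) -> Tensor:
        c, bc, (k1, k2), fk = self.cfg_shape
        if x.shape[1] != c:
            raise InvalidConfigError(
                f"dual-channel block built for {c} channels, input has {x.shape[1]}"
            )
        return dual_channel_t(
            x, self.w1, self.b1, self.w2, self.b2, self.w_fuse, self.b_fuse,
            self.sa_weight, self.sa_bias, k1, k2, fk, self.sa_padding,
        )
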