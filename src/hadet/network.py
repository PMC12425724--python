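"""Instantiate a declarative :class:`~hadet.architecture.ModelSpec` as a
runnable, trainable network.

Every node kind maps to a module whose learned tensors correspond one-to-one
with the closed-form signatures in :mod:`hadet.architecture`, so
``model.num_params()`` equals ``count_params(spec).params_total`` exactly —
the profiler and the runtime network cannot drift apart.

The three detection heads emit, per scale, a box tensor of ``4 * reg_max``
discretized side-offset logits and a class-logit tensor; decoding (softmax
expectation over the bins, anchor offsetting) lives in
:mod:`hadet.train_eval`.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .architecture import REG_MAX, ModelSpec
from .attention import DualChannelModule, Shuffle3DModule, SpatialAttentionModule
from .nn import ConvBNSiLU, DWConv, Module, Tensor

__all__ = ["DetectionModel", "instantiate"]


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, k=3, e=0.5, rng=None):
        super().__init__()
        ch = int(c2 * e)
        self.cv1 = ConvBNSiLU(c1, ch, k, rng=rng)
        self.cv2 = ConvBNSiLU(ch, c2, k, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3k(Module):
    def __init__(self, c1, c2, n=2, rng=None):
        super().__init__()
        ch = int(c2 * 0.5)
        self.cv1 = ConvBNSiLU(c1, ch, 1, rng=rng)
        self.cv2 = ConvBNSiLU(c1, ch, 1, rng=rng)
        self.cv3 = ConvBNSiLU(2 * ch, c2, 1, rng=rng)
        self.m = nn.Sequential(*[Bottleneck(ch, ch, True, k=3, e=1.0, rng=rng)
                                 for _ in range(n)])

    def forward(self, x):
        return self.cv3(Tensor.concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class C3K2(Module):
    """Staged block: split, run n inner blocks on one half, fuse everything."""

    def __init__(self, c1, c2, n=1, c3k=False, e=0.5, rng=None):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = ConvBNSiLU(c1, 2 * self.c, 1, rng=rng)
        self.cv2 = ConvBNSiLU((2 + n) * self.c, c2, 1, rng=rng)
        self.m = nn.ModuleList(
            [C3k(self.c, self.c, 2, rng=rng) if c3k
             else Bottleneck(self.c, self.c, True, k=3, e=0.5, rng=rng)
             for _ in range(n)]
        )

    def forward(self, x):
        y = self.cv1(x)
        parts = [y[:, : self.c], y[:, self.c :]]
        for blk in self.m:
            parts.append(blk(parts[-1]))
        return self.cv2(Tensor.concat(parts, axis=1))


class SPPF(Module):
    def __init__(self, c1, c2, k=5, rng=None):
        super().__init__()
        ch = c1 // 2
        self.cv1 = ConvBNSiLU(c1, ch, 1, rng=rng)
        self.cv2 = ConvBNSiLU(4 * ch, c2, 1, rng=rng)
        self.k = k

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(y[-1].maxpool2d(self.k, 1, self.k // 2))
        return self.cv2(Tensor.concat(y, axis=1))


class MultiHeadSelfAttention(Module):
    """Windowless multi-head self-attention with a depthwise positional
    encoding on the value path (the C2PSA inner attention)."""

    def __init__(self, dim, num_heads, attn_ratio=0.5, rng=None):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim ** -0.5
        nh_kd = self.key_dim * num_heads
        self.qkv = ConvBNSiLU(dim, dim + 2 * nh_kd, 1, act=False, rng=rng)
        self.proj = ConvBNSiLU(dim, dim, 1, act=False, rng=rng)
        self.pe = ConvBNSiLU(dim, dim, 3, groups=dim, act=False, rng=rng)
        self.dim = dim

    def forward(self, x):
        b, c, h, w = x.shape
        n = h * w
        qkv = self.qkv(x).reshape(b, self.num_heads,
                                  2 * self.key_dim + self.head_dim, n)
        q = qkv[:, :, : self.key_dim]
        k = qkv[:, :, self.key_dim : 2 * self.key_dim]
        v = qkv[:, :, 2 * self.key_dim :]
        attn = (q.transpose(0, 1, 3, 2) @ k) * self.scale
        attn = attn.softmax(axis=-1)
        out = (v @ attn.transpose(0, 1, 3, 2)).reshape(b, c, h, w)
        out = out + self.pe(v.reshape(b, c, h, w))
        return self.proj(out)


class PSABlock(Module):
    def __init__(self, c, num_heads, rng=None):
        super().__init__()
        self.attn = MultiHeadSelfAttention(c, num_heads, rng=rng)
        self.ffn = nn.Sequential(ConvBNSiLU(c, 2 * c, 1, rng=rng),
                                 ConvBNSiLU(2 * c, c, 1, act=False, rng=rng))

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.ffn(x)


class C2PSA(Module):
    def __init__(self, c1, n=1, rng=None):
        super().__init__()
        self.c = int(c1 * 0.5)
        self.cv1 = ConvBNSiLU(c1, 2 * self.c, 1, rng=rng)
        self.cv2 = ConvBNSiLU(2 * self.c, c1, 1, rng=rng)
        self.m = nn.Sequential(*[PSABlock(self.c, max(1, self.c // 64), rng=rng)
                                 for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        a, b = y[:, : self.c], y[:, self.c :]
        return self.cv2(Tensor.concat([a, self.m(b)], axis=1))


class DetectHead(Module):
    """Decoupled per-scale head: box branch (offset-bin logits) and class
    branch (per-class logits).  Either branch's first convolution may be the
    parameter-free Shuffle3D gate, in which case the following convolution
    takes the head's full incoming width."""

    def __init__(self, cin, nc, c2, c3, reg_max=REG_MAX,
                 shuffle3d_box=False, shuffle3d_cls=False,
                 include_dfl=False, rng=None):
        super().__init__()
        if shuffle3d_box:
            box = [Shuffle3DModule(cin), ConvBNSiLU(cin, c2, 3, rng=rng)]
        else:
            box = [ConvBNSiLU(cin, c2, 3, rng=rng), ConvBNSiLU(c2, c2, 3, rng=rng)]
        box.append(nn.Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng))
        self.box_branch = nn.Sequential(*box)
        cls = [Shuffle3DModule(cin)] if shuffle3d_cls else [DWConv(cin, 3, rng=rng)]
        cls += [
            ConvBNSiLU(cin, c3, 1, rng=rng),
            DWConv(c3, 3, rng=rng),
            ConvBNSiLU(c3, c3, 1, rng=rng),
            nn.Conv2d(c3, nc, 1, bias=True, rng=rng),
        ]
        self.cls_branch = nn.Sequential(*cls)
        self.reg_max = reg_max
        if include_dfl:
            # frozen integral-decoding projection over the offset bins
            self.dfl_proj = np.arange(reg_max, dtype=np.float32)
            self.frozen_param_count = reg_max

    def forward(self, x):
        return self.box_branch(x), self.cls_branch(x)


class DetectionModel(Module):
    """Graph executor over the spec's node list."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        self.head_indices = spec.head_indices
        blocks: list[Module] = []
        for node in spec.nodes:
            a = node.args
            if node.kind == "CBS":
                blocks.append(ConvBNSiLU(node.cin, a["cout"], a.get("k", 3),
                                         a.get("s", 1), rng=rng))
            elif node.kind == "C3K2":
                blocks.append(C3K2(node.cin, a["cout"], a.get("n", 1),
                                   a.get("c3k", False), a.get("e", 0.5), rng=rng))
            elif node.kind == "SPPF":
                blocks.append(SPPF(node.cin, a["cout"], rng=rng))
            elif node.kind == "C2PSA":
                blocks.append(C2PSA(node.cin, a.get("n", 1), rng=rng))
            elif node.kind == "DualChannel":
                blocks.append(DualChannelModule(
                    node.cin, rng=rng,
                    branch_channels=a.get("branch_channels"),
                    branch_kernels=a.get("branch_kernels", (3, 5)),
                    fuse_kernel=a.get("fuse_kernel", 1)))
            elif node.kind == "SpatialAttention":
                blocks.append(SpatialAttentionModule(a.get("k", 7), rng=rng))
            elif node.kind == "Shuffle3D":
                blocks.append(Shuffle3DModule(node.cin))
            elif node.kind == "Upsample":
                blocks.append(nn.Upsample2())
            elif node.kind == "Concat":
                blocks.append(nn.Identity())  # handled in forward
            elif node.kind == "DetectHead":
                blocks.append(DetectHead(
                    node.cin, a["nc"], a["c2"], a["c3"], a.get("reg_max", REG_MAX),
                    a.get("shuffle3d_box", False), a.get("shuffle3d_cls", False),
                    a.get("include_dfl", False), rng=rng))
            else:  # pragma: no cover - guarded by ModelSpec validation
                raise ValueError(f"unknown node kind {node.kind}")
        self.blocks = nn.ModuleList(blocks)

    @property
    def num_classes(self) -> int:
        return self.spec.num_classes

    @property
    def dfl_proj(self) -> np.ndarray:
        for idx in self.head_indices:
            blk = self.blocks[idx]
            if hasattr(blk, "dfl_proj"):
                return blk.dfl_proj
        raise AttributeError("no head carries the offset-bin projection")

    def forward(self, x: Tensor) -> list[tuple[Tensor, Tensor]]:
        cache: dict[int, Tensor] = {-1: x}
        outputs = []
        needed: dict[int, int] = {}
        for node in self.spec.nodes:
            for s in node.from_idx:
                needed[s] = needed.get(s, 0) + 1
        for node, blk in zip(self.spec.nodes, self.blocks):
            srcs = [cache[i] for i in node.from_idx]
            if node.kind == "Concat":
                out = Tensor.concat(srcs, axis=1)
            else:
                out = blk(srcs[0])
            cache[node.index] = out
            if node.kind == "DetectHead":
                outputs.append(out)
            for s in node.from_idx:  # free activations no longer needed
                needed[s] -= 1
                if needed[s] == 0 and s not in self.spec.head_indices:
                    cache.pop(s, None)
        return outputs


def instantiate(spec: ModelSpec, seed: int = 0) -> DetectionModel:
    """Build a model from a spec with seeded He initialization."""
    return DetectionModel(spec, np.random.default_rng(seed))
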