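"""Declarative detector graphs and closed-form parameter/FLOP profiling.

The baseline graph is the public YOLOv11 layout at the *n* scale (width 0.25,
depth 0.50, max channel width 1024): a CBS/C3K2 backbone ending in SPPF and a
C2PSA attention block, an FPN-style neck fusing strides 8/16/32 with nearest
upsampling and concatenation, and three decoupled detection heads (a CBS box
branch regressing discretized side offsets, a depthwise-separable class
branch).  The modified variant replaces C2PSA with the Dual-channel attention
block, replaces the first convolution of each head branch with the
parameter-free Shuffle3D gate, and adds a Spatial attention gate on the
network input.

Profiling is exact closed-form arithmetic over the primitive convolutions of
every node; FLOPs are reported as 2 x the operation count of convolution
kernels, conv biases and batch-norm scale/shift (2 ops per normalized
element), the accounting used by the standard conv profilers this model
family is reported with.  Activations, pooling and the attention matmuls
inside C2PSA are not counted.  The same per-node signatures drive
:mod:`hadet.network`, so the instantiated model's tensor count agrees with the
closed form exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import gcd
from typing import Iterator

__all__ = [
    "ConvSig",
    "LayerNode",
    "ModelSpec",
    "ProfileReport",
    "build_baseline",
    "build_ha",
    "build_variant",
    "count_params",
    "count_flops",
    "make_divisible",
]

REG_MAX = 16
STRIDES = (8, 16, 32)


def make_divisible(x: float, divisor: int = 8) -> int:
    """Round channel width up to the nearest multiple of ``divisor``."""
    return max(divisor, int(x + divisor / 2) // divisor * divisor)


@dataclass(frozen=True)
class ConvSig:
    """One primitive convolution: the unit of parameter/MAC accounting."""

    cin: int
    cout: int
    k: int = 1
    groups: int = 1
    bias: bool = False
    bn: bool = True  # batch norm contributes 2*cout learned params, 0 MACs
    frozen: bool = False  # counted in params_total, excluded from trainables

    @property
    def weight_numel(self) -> int:
        return self.k * self.k * (self.cin // self.groups) * self.cout

    @property
    def params(self) -> int:
        n = self.weight_numel
        if self.bias:
            n += self.cout
        if self.bn:
            n += 2 * self.cout
        return n

    def macs(self, hw: int) -> int:
        # kernel multiply-accumulates plus bias adds and the per-element
        # normalization scale/shift, matching the standard conv profiler
        n = self.weight_numel * hw
        if self.bias:
            n += self.cout * hw
        if self.bn:
            n += 2 * self.cout * hw
        return n


@dataclass
class LayerNode:
    index: int
    kind: str
    from_idx: tuple[int, ...]
    args: dict = field(default_factory=dict)
    # resolved during graph validation
    cin: int = 0
    cout: int = 0
    out_hw: tuple[int, int] = (0, 0)

    def conv_sigs(self) -> list[ConvSig]:
        return _KIND_SIGS[self.kind](self.cin, self.cout, self.args)

    @property
    def params(self) -> int:
        return sum(s.params for s in self.conv_sigs())

    def macs(self) -> int:
        hw = self.out_hw[0] * self.out_hw[1]
        if self.kind == "DetectHead":
            return _detect_macs(self.cin, self.args, hw)
        return sum(s.macs(hw) for s in self.conv_sigs())


# ---------------------------------------------------------------------------
# primitive signatures per node kind
# ---------------------------------------------------------------------------


def _cbs(cin: int, cout: int, k: int = 1) -> ConvSig:
    return ConvSig(cin, cout, k, bn=True)


def _dwc(c: int, k: int = 3) -> ConvSig:
    return ConvSig(c, c, k, groups=c, bn=True)


def _bottleneck(c1: int, c2: int, k: int = 3, e: float = 0.5) -> list[ConvSig]:
    ch = int(c2 * e)
    return [_cbs(c1, ch, k), _cbs(ch, c2, k)]


def _c3k(c1: int, c2: int, n: int = 2) -> list[ConvSig]:
    ch = int(c2 * 0.5)
    sigs = [_cbs(c1, ch, 1), _cbs(c1, ch, 1), _cbs(2 * ch, c2, 1)]
    for _ in range(n):
        sigs += _bottleneck(ch, ch, k=3, e=1.0)
    return sigs


def _sigs_cbs(cin: int, cout: int, args: dict) -> list[ConvSig]:
    return [_cbs(cin, cout, args.get("k", 3))]


def _sigs_c3k2(cin: int, cout: int, args: dict) -> list[ConvSig]:
    e = args.get("e", 0.5)
    n = args.get("n", 1)
    c = int(cout * e)
    sigs = [_cbs(cin, 2 * c, 1), _cbs((2 + n) * c, cout, 1)]
    for _ in range(n):
        sigs += _c3k(c, c) if args.get("c3k") else _bottleneck(c, c)
    return sigs


def _sigs_sppf(cin: int, cout: int, args: dict) -> list[ConvSig]:
    c = cin // 2
    return [_cbs(cin, c, 1), _cbs(4 * c, cout, 1)]


def _sigs_c2psa(cin: int, cout: int, args: dict) -> list[ConvSig]:
    n = args.get("n", 1)
    c = int(cin * 0.5)
    heads = max(1, c // 64)
    key_dim = int(c // heads * 0.5)
    h = c + 2 * key_dim * heads
    sigs = [_cbs(cin, 2 * c, 1), _cbs(2 * c, cin, 1)]
    for _ in range(n):
        sigs += [
            _cbs(c, h, 1),               # fused query/key/value projection
            _cbs(c, c, 1),               # output projection
            _dwc(c, 3),                  # positional encoding on values
            _cbs(c, 2 * c, 1),           # feed-forward expand
            _cbs(2 * c, c, 1),           # feed-forward contract
        ]
    return sigs


def _sigs_dualchannel(cin: int, cout: int, args: dict) -> list[ConvSig]:
    bc = args.get("branch_channels") or cin // 8
    k1, k2 = args.get("branch_kernels", (3, 5))
    fk = args.get("fuse_kernel", 1)
    plain = dict(bias=True, bn=False)
    return [
        ConvSig(cin, bc, k1, **plain),
        ConvSig(cin, bc, k2, **plain),
        ConvSig(2 * bc, cin, fk, **plain),
        ConvSig(2, 1, args.get("sa_kernel", 7), **plain),
    ]


def _sigs_spatial(cin: int, cout: int, args: dict) -> list[ConvSig]:
    return [ConvSig(2, 1, args.get("k", 7), bias=True, bn=False)]


def _sigs_none(cin: int, cout: int, args: dict) -> list[ConvSig]:
    return []


def _detect_branch_sigs(x: int, args: dict) -> tuple[list[ConvSig], list[ConvSig]]:
    """(box branch, class branch) primitive convolutions for one head."""
    nc = args["nc"]
    reg_max = args.get("reg_max", REG_MAX)
    # branch widths are shared across the three heads, derived from the
    # narrowest (stride-8) incoming width
    c2 = args.get("c2") or max(16, x // 4, reg_max * 4)
    c3 = args.get("c3") or max(x, min(nc, 100))
    if args.get("shuffle3d_box"):
        box = [_cbs(x, c2, 3)]  # Shuffle3D keeps x channels; next conv widened
    else:
        box = [_cbs(x, c2, 3), _cbs(c2, c2, 3)]
    box.append(ConvSig(c2, 4 * reg_max, 1, bias=True, bn=False))
    cls: list[ConvSig] = []
    if not args.get("shuffle3d_cls"):
        cls.append(ConvSig(x, x, 3, groups=gcd(x, x), bn=True))  # depthwise
    cls += [
        _cbs(x, c3, 1),
        _dwc(c3, 3),
        _cbs(c3, c3, 1),
        ConvSig(c3, nc, 1, bias=True, bn=False),
    ]
    return box, cls


def _sigs_detect(cin: int, cout: int, args: dict) -> list[ConvSig]:
    box, cls = _detect_branch_sigs(cin, args)
    sigs = box + cls
    if args.get("include_dfl"):
        sigs.append(ConvSig(REG_MAX, 1, 1, bias=False, bn=False, frozen=True))
    return sigs


def _detect_macs(cin: int, args: dict, hw: int) -> int:
    box, cls = _detect_branch_sigs(cin, args)
    total = sum(s.macs(hw) for s in box + cls)
    if args.get("include_dfl"):
        total += REG_MAX * 4 * hw  # integral decoding conv over the bins
    return total


_KIND_SIGS = {
    "CBS": _sigs_cbs,
    "C3K2": _sigs_c3k2,
    "SPPF": _sigs_sppf,
    "C2PSA": _sigs_c2psa,
    "DualChannel": _sigs_dualchannel,
    "SpatialAttention": _sigs_spatial,
    "Shuffle3D": _sigs_none,
    "Upsample": _sigs_none,
    "Concat": _sigs_none,
    "DetectHead": _sigs_detect,
}


# ---------------------------------------------------------------------------
# model specs
# ---------------------------------------------------------------------------


class SpecError(ValueError):
    """Raised for malformed model specifications or profile configs."""


@dataclass
class ModelSpec:
    """Ordered DAG of :class:`LayerNode`; the object that is profiled."""

    name: str
    nodes: list[LayerNode]
    num_classes: int
    input_size: int = 640
    width: float = 0.25
    depth: float = 0.5

    def __post_init__(self) -> None:
        self.resolve(self.input_size)

    def resolve(self, input_size: int) -> None:
        """Propagate channel counts and spatial sizes through the graph."""
        if input_size % 32:
            raise SpecError(f"input_size {input_size} not divisible by 32")
        shapes: dict[int, tuple[int, int, int]] = {-1: (3, input_size, input_size)}
        for node in self.nodes:
            for src in node.from_idx:
                if src >= node.index:
                    raise SpecError(f"node {node.index} draws from later node {src}")
            srcs = [shapes[i] for i in node.from_idx]
            c, h, w = srcs[0]
            if node.kind == "Concat":
                if any(s[1:] != (h, w) for s in srcs):
                    raise SpecError(f"concat at node {node.index}: mismatched sizes")
                c_out, h_out, w_out = sum(s[0] for s in srcs), h, w
            elif node.kind == "CBS":
                s = node.args.get("s", 1)
                c_out, h_out, w_out = node.args["cout"], h // s, w // s
            elif node.kind == "Upsample":
                c_out, h_out, w_out = c, 2 * h, 2 * w
            elif node.kind in ("C3K2", "SPPF"):
                c_out, h_out, w_out = node.args["cout"], h, w
            elif node.kind == "DetectHead":
                c_out, h_out, w_out = 4 * REG_MAX + self.num_classes, h, w
            else:  # shape-preserving attention blocks
                c_out, h_out, w_out = c, h, w
            node.cin, node.cout, node.out_hw = c, c_out, (h_out, w_out)
            shapes[node.index] = (c_out, h_out, w_out)
        heads = [n for n in self.nodes if n.kind == "DetectHead"]
        if len(heads) != 3:
            raise SpecError(f"expected 3 detection heads, found {len(heads)}")
        self.head_indices = tuple(n.index for n in heads)

    def num_anchors(self, input_size: int | None = None) -> int:
        """Candidate predictions emitted by the three heads."""
        s = input_size or self.input_size
        if s % 32:
            raise SpecError(f"input_size {s} not divisible by 32")
        return sum((s // st) ** 2 for st in STRIDES)


@dataclass
class ProfileReport:
    model: str
    params_total: int
    macs: int | None = None
    input_size: int | None = None
    rows: list[dict] = field(default_factory=list)

    @property
    def params_millions(self) -> float:
        return round(self.params_total / 1e6, 2)

    @property
    def gflops(self) -> float | None:
        if self.macs is None:
            return None
        return round(2 * self.macs / 1e9, 1)

    @property
    def gflops_raw(self) -> float | None:
        return None if self.macs is None else 2 * self.macs / 1e9

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "params_total": self.params_total,
                "params_millions": self.params_millions,
                "macs": self.macs,
                "gflops": self.gflops,
                "input_size": self.input_size,
                "nodes": self.rows,
            },
            indent=2,
        )

    def to_table(self) -> str:
        lines = [f"{'idx':>4} {'kind':<18} {'from':<12} {'out':>14} {'params':>10} {'macs':>14}"]
        for r in self.rows:
            lines.append(
                f"{r['index']:>4} {r['kind']:<18} {str(r['from']):<12} "
                f"{str(r['out_shape']):>14} {r['params']:>10} {r['macs']:>14}"
            )
        lines.append(
            f"total: {self.params_total} params ({self.params_millions} M)"
            + (f", {self.gflops} GFLOPs @ {self.input_size}" if self.macs is not None else "")
        )
        return "\n".join(lines)


def _iter_rows(spec: ModelSpec, with_macs: bool) -> Iterator[dict]:
    for node in spec.nodes:
        yield {
            "index": node.index,
            "kind": node.kind,
            "from": list(node.from_idx),
            "out_shape": [node.cout, *node.out_hw],
            "params": node.params,
            "macs": node.macs() if with_macs else None,
        }


def count_params(spec: ModelSpec) -> ProfileReport:
    """Exact learned-tensor count (conv kernels, biases, norm affine pairs)."""
    rows = list(_iter_rows(spec, with_macs=False))
    return ProfileReport(spec.name, sum(r["params"] for r in rows), rows=rows)


def count_flops(spec: ModelSpec, input_size: int = 640) -> ProfileReport:
    """Params plus MACs/GFLOPs at ``input_size`` (2xMACs, conv work only)."""
    if input_size % 32:
        raise SpecError(f"input_size {input_size} not divisible by 32")
    spec.resolve(input_size)
    rows = list(_iter_rows(spec, with_macs=True))
    rep = ProfileReport(
        spec.name,
        sum(r["params"] for r in rows),
        macs=sum(r["macs"] for r in rows),
        input_size=input_size,
        rows=rows,
    )
    spec.resolve(spec.input_size)
    return rep


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _scaled(c: int, width: float, max_channels: int) -> int:
    return make_divisible(min(c, max_channels) * width, 8)


def build_variant(
    num_classes: int = 4,
    *,
    dual_channel: bool = False,
    shuffle3d_heads: bool = False,
    spatial_input: bool = False,
    input_size: int = 640,
    width: float = 0.25,
    depth: float = 0.5,
    max_channels: int = 1024,
    dc_branch_channels: int | None = None,
    name: str | None = None,
) -> ModelSpec:
    """Assemble the baseline graph with optional attention substitutions.

    ``dual_channel`` swaps the post-SPPF C2PSA block for Dual-channel
    attention of equal in/out width; ``shuffle3d_heads`` swaps the first
    convolution of each head branch (CBS on the box side, depthwise on the
    class side) for the parameter-free Shuffle3D gate, widening the following
    convolution to the head's incoming channel count; ``spatial_input`` gates
    the raw network input with Spatial attention.
    """
    if num_classes < 1:
        raise SpecError("num_classes must be >= 1")

    def ch(c: int) -> int:
        return _scaled(c, width, max_channels)

    n_rep = max(1, round(2 * depth))  # repeat count of every staged block
    nodes: list[LayerNode] = []
    idx = 0

    def add(kind: str, frm: tuple[int, ...], **args) -> int:
        nonlocal idx
        nodes.append(LayerNode(idx, kind, frm, args))
        idx += 1
        return idx - 1

    prev = -1
    if spatial_input:
        prev = add("SpatialAttention", (prev,))
    # backbone
    prev = add("CBS", (prev,), cout=ch(64), k=3, s=2)                    # P1
    prev = add("CBS", (prev,), cout=ch(128), k=3, s=2)                   # P2
    prev = add("C3K2", (prev,), cout=ch(256), n=n_rep, c3k=False, e=0.25)
    prev = add("CBS", (prev,), cout=ch(256), k=3, s=2)                   # P3
    p3 = prev = add("C3K2", (prev,), cout=ch(512), n=n_rep, c3k=False, e=0.25)
    prev = add("CBS", (prev,), cout=ch(512), k=3, s=2)                   # P4
    p4 = prev = add("C3K2", (prev,), cout=ch(512), n=n_rep, c3k=True)
    prev = add("CBS", (prev,), cout=ch(1024), k=3, s=2)                  # P5
    prev = add("C3K2", (prev,), cout=ch(1024), n=n_rep, c3k=True)
    prev = add("SPPF", (prev,), cout=ch(1024))
    if dual_channel:
        p5 = prev = add(
            "DualChannel", (prev,), branch_channels=dc_branch_channels,
            branch_kernels=(3, 5), fuse_kernel=1,
        )
    else:
        p5 = prev = add("C2PSA", (prev,), n=n_rep)
    # neck (FPN top-down, then bottom-up)
    prev = add("Upsample", (prev,))
    prev = add("Concat", (prev, p4))
    t4 = prev = add("C3K2", (prev,), cout=ch(512), n=n_rep, c3k=False)
    prev = add("Upsample", (prev,))
    prev = add("Concat", (prev, p3))
    n3 = prev = add("C3K2", (prev,), cout=ch(256), n=n_rep, c3k=False)   # out P3
    prev = add("CBS", (prev,), cout=ch(256), k=3, s=2)
    prev = add("Concat", (prev, t4))
    n4 = prev = add("C3K2", (prev,), cout=ch(512), n=n_rep, c3k=False)   # out P4
    prev = add("CBS", (prev,), cout=ch(512), k=3, s=2)
    prev = add("Concat", (prev, p5))
    n5 = prev = add("C3K2", (prev,), cout=ch(1024), n=n_rep, c3k=True)   # out P5
    # decoupled heads, one per stride
    head_c2 = max(16, ch(256) // 4, REG_MAX * 4)
    head_c3 = max(ch(256), min(num_classes, 100))
    for i, src in enumerate((n3, n4, n5)):
        add(
            "DetectHead", (src,), nc=num_classes, reg_max=REG_MAX,
            c2=head_c2, c3=head_c3,
            shuffle3d_box=shuffle3d_heads, shuffle3d_cls=shuffle3d_heads,
            include_dfl=(i == 0),
        )
    if name is None:
        tags = [t for f, t in [(dual_channel, "dc"), (shuffle3d_heads, "s3d"),
                               (spatial_input, "sp")] if f]
        name = "yolov11n" + ("-" + "+".join(tags) if tags else "")
    return ModelSpec(name, nodes, num_classes, input_size, width, depth)


def build_baseline(num_classes: int = 4, **kw) -> ModelSpec:
    """The unmodified single-stage baseline at the *n* scale."""
    return build_variant(num_classes, name=kw.pop("name", "yolov11n"), **kw)


def build_ha(num_classes: int = 4, **kw) -> ModelSpec:
    """The modified detector: Dual-channel for C2PSA, Shuffle3D on the head
    branches, Spatial attention gating the input."""
    return build_variant(
        num_classes,
        dual_channel=True,
        shuffle3d_heads=True,
        spatial_input=True,
        name=kw.pop("name", "yolov11n-ha"),
        **kw,
    )
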