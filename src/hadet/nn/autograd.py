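"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the detector needs: broadcasting
elementwise arithmetic, reductions, matmul, 2-D convolution (dense, grouped
and depthwise), max pooling, nearest upsampling, softmax, and the
sigmoid/SiLU nonlinearities.  Gradients propagate through a dynamically
recorded tape; ``backward()`` runs a topological sweep.

Float32 is the working dtype; float64 inputs are preserved so closed-form
gradient checks can run at full precision.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype == np.float64:
        return a
    return a.astype(np.float32, copy=False)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer mixed expressions to the reflected Tensor operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free the closure early

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._wrap(other)
        out_data = a.data + b.data

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(out_data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._wrap(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._wrap(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, p: float):
        a = self

        def bwd(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data**p, (a,), bwd)

    def __matmul__(self, other):
        a, b = self, Tensor._wrap(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    def __getitem__(self, idx):
        a = self
        parts = idx if isinstance(idx, tuple) else (idx,)
        has_array = any(isinstance(p, (np.ndarray, list)) for p in parts)

        def bwd(g):
            full = np.zeros_like(a.data)
            if has_array:
                np.add.at(full, idx, g)  # general fancy indexing may repeat
            else:
                full[idx] += g
            a._accum(full)

        return Tensor._make(a.data[idx], (a,), bwd)

    # -- elementwise functions ------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bwd(g):
            a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bwd)

    def arctan(self):
        a = self

        def bwd(g):
            a._accum(g / (1.0 + a.data * a.data))

        return Tensor._make(np.arctan(a.data), (a,), bwd)

    def sigmoid(self):
        a = self
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bwd)

    def silu(self):
        a = self
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-a.data))
        out_data = a.data * s

        def bwd(g):
            a._accum(g * s * (1.0 + a.data * (1.0 - s)))

        return Tensor._make(out_data, (a,), bwd)

    def clip(self, lo: float, hi: float):
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def bwd(g):
            a._accum(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), bwd)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[i] for i in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        a = self
        out_data = a.data.max(axis=axis, keepdims=True)
        mask = a.data == out_data
        # split gradient between ties, mirroring subgradient choice
        counts = mask.sum(axis=axis, keepdims=True)

        def bwd(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accum(mask * (gg / counts))

        res = out_data if keepdims else out_data.squeeze(axis=axis)
        return Tensor._make(res, (a,), bwd)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            a._accum(g.reshape(a.shape))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 1) -> "Tensor":
        ts = [Tensor._wrap(t) for t in tensors]
        sizes = [t.shape[axis] for t in ts]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        return Tensor._make(
            np.concatenate([t.data for t in ts], axis=axis), ts, bwd
        )

    # -- spatial ops -----------------------------------------------------
    def pad2d(self, p: int):
        a = self
        if p == 0:
            return a

        def bwd(g):
            a._accum(g[:, :, p:-p, p:-p])

        return Tensor._make(
            np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p))), (a,), bwd
        )

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, groups: int = 1) -> "Tensor":
        return _conv2d(self, weight, bias, stride, padding, groups)

    def maxpool2d(self, k: int, stride: int = 1, padding: int = 0) -> "Tensor":
        return _maxpool2d(self, k, stride, padding)

    def upsample2(self) -> "Tensor":
        """Nearest-neighbour x2 upsampling."""
        a = self

        def bwd(g):
            b_, c, h2, w2 = g.shape
            a._accum(
                g.reshape(b_, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            )

        return Tensor._make(
            np.repeat(np.repeat(a.data, 2, axis=2), 2, axis=3), (a,), bwd
        )

    def batchnorm_train(self, gamma: "Tensor", beta: "Tensor",
                        eps: float = 1e-3):
        """Fused training-mode batch normalization over axes (0, 2, 3).

        Returns ``(out, mean, biased_var)`` with the statistics as plain
        arrays for the caller's running estimates.
        """
        x = self
        n = x.size // x.shape[1]
        mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
        xc = x.data - mu
        var = np.mean(xc * xc, axis=(0, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xn = xc * inv
        g4 = gamma.data.reshape(1, -1, 1, 1)
        out_data = xn * g4 + beta.data.reshape(1, -1, 1, 1)

        def bwd(g):
            if gamma.requires_grad:
                gamma._accum((g * xn).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gm = g.mean(axis=(0, 2, 3), keepdims=True)
                gxn = (g * xn).mean(axis=(0, 2, 3), keepdims=True)
                x._accum((g4 * inv) * (g - gm - xn * gxn))

        out = Tensor._make(out_data, (x, gamma, beta), bwd)
        return out, mu.reshape(-1), var.reshape(-1) * (n / max(n - 1, 1))

    def softmax(self, axis: int = -1) -> "Tensor":
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        e = np.exp(a.data - m)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accum(s * (g - dot))

        return Tensor._make(s, (a,), bwd)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


# ---------------------------------------------------------------------------
# convolution internals
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(B, C, Hp, Wp) -> (C*kh*kw, B*Ho*Wo) patch matrix (single-gemm layout)."""
    b, c, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, kh, kw)
    cols = win.transpose(1, 4, 5, 0, 2, 3).reshape(c * kh * kw, b * ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int):
    """Fold a (C*kh*kw, B*Ho*Wo) gradient back onto the padded input."""
    b, c, hp, wp = xshape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    dxp = np.zeros(xshape, dtype=dcols.dtype)
    d = dcols.reshape(c, kh, kw, b, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                d[:, i, j].transpose(1, 0, 2, 3)
            )
    return dxp


def _conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int,
            padding: int, groups: int) -> Tensor:
    cout, cin_g, kh, kw = w.shape
    bsz, cin, _, _ = x.shape
    if cin % groups or cout % groups or cin // groups != cin_g:
        raise ValueError(
            f"conv2d: {cin} input channels incompatible with groups={groups} "
            f"and weight {w.shape}"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data

    if groups == cin and cin_g == 1:  # depthwise fast path: shifted adds
        mult = cout // cin
        ho = (xp.shape[2] - kh) // stride + 1
        wo = (xp.shape[3] - kw) // stride + 1
        out = np.zeros((bsz, cout, ho, wo), dtype=xp.dtype)
        wd = w.data.reshape(cin, mult, kh, kw)
        for i in range(kh):
            for j in range(kw):
                sl = xp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride]
                # (B, C, Ho, Wo) * (C, mult) -> (B, C*mult, Ho, Wo)
                out += (sl[:, :, None] * wd[None, :, :, i, j, None, None]).reshape(
                    bsz, cout, ho, wo
                )
        if b is not None:
            out += b.data.reshape(1, cout, 1, 1)

        def bwd_dw(g):
            gr = g.reshape(bsz, cin, mult, ho, wo)
            if w.requires_grad:
                dw = np.zeros_like(w.data).reshape(cin, mult, kh, kw)
                for i in range(kh):
                    for j in range(kw):
                        sl = xp[:, :, i : i + ho * stride : stride,
                                j : j + wo * stride : stride]
                        if mult == 1:
                            dw[:, 0, i, j] = (sl * gr[:, :, 0]).sum(axis=(0, 2, 3))
                        else:
                            dw[:, :, i, j] = np.einsum("bchw,bcmhw->cm", sl, gr)
                w._accum(dw.reshape(w.shape))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                wr = w.data.reshape(cin, mult, kh, kw)
                for i in range(kh):
                    for j in range(kw):
                        if mult == 1:
                            contrib = gr[:, :, 0] * wr[None, :, 0, i, j, None, None]
                        else:
                            contrib = np.einsum("bcmhw,cm->bchw", gr, wr[:, :, i, j])
                        dxp[:, :, i : i + ho * stride : stride,
                            j : j + wo * stride : stride] += contrib
                x._accum(dxp[:, :, padding : xp.shape[2] - padding,
                             padding : xp.shape[3] - padding] if padding else dxp)

        parents = (x, w) if b is None else (x, w, b)
        return Tensor._make(out, parents, bwd_dw)

    if groups == 1:
        cols, ho, wo = _im2col(xp, kh, kw, stride)
        wmat = w.data.reshape(cout, cin_g * kh * kw)
        out = np.ascontiguousarray(
            (wmat @ cols).reshape(cout, bsz, ho, wo).transpose(1, 0, 2, 3)
        )
        if b is not None:
            out += b.data.reshape(1, cout, 1, 1)

        def bwd(g):
            gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(cout, -1)
            if w.requires_grad:
                w._accum((gmat @ cols.T).reshape(w.shape))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dcols = wmat.T @ gmat
                dxp = _col2im(dcols, xp.shape, kh, kw, stride)
                x._accum(dxp[:, :, padding : xp.shape[2] - padding,
                             padding : xp.shape[3] - padding] if padding else dxp)

        parents = (x, w) if b is None else (x, w, b)
        return Tensor._make(out, parents, bwd)

    # general grouped conv: loop over groups (rare in this model family)
    xs = x if isinstance(x, Tensor) else Tensor(x)
    chunks = []
    cpg_in, cpg_out = cin // groups, cout // groups
    for gidx in range(groups):
        xg = xs[:, gidx * cpg_in : (gidx + 1) * cpg_in]
        wg = w[gidx * cpg_out : (gidx + 1) * cpg_out]
        bg = None if b is None else b[gidx * cpg_out : (gidx + 1) * cpg_out]
        chunks.append(_conv2d(xg, wg, bg, stride, padding, 1))
    return Tensor.concat(chunks, axis=1)


def _maxpool2d(x: Tensor, k: int, stride: int, padding: int) -> Tensor:
    xp = np.pad(
        x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    ) if padding else x.data
    b, c, hp, wp = xp.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride].reshape(b, c, ho, wo, k * k)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        dxp = np.zeros((b, c, hp, wp), dtype=g.dtype)
        ii, jj = np.unravel_index(idx, (k, k))
        bi, ci, hi, wi = np.indices(idx.shape)
        np.add.at(dxp, (bi, ci, hi * stride + ii, wi * stride + jj), g)
        x._accum(
            dxp[:, :, padding : hp - padding, padding : wp - padding]
            if padding else dxp
        )

    return Tensor._make(out, (x,), bwd)
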