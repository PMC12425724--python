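"""Neural network building blocks over the autograd engine.

Mirrors the conventional conv/BN/SiLU vocabulary of single-stage detectors.
Parameter initialization is He-style for conv kernels and is driven by an
explicit ``numpy.random.Generator`` so builds are reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Sequential",
    "ModuleList",
    "Conv2d",
    "BatchNorm2d",
    "SiLU",
    "Sigmoid",
    "Identity",
    "MaxPool2d",
    "Upsample2",
    "ConvBNSiLU",
    "DWConv",
    "SGD",
]


class Module:
    """Base class: parameter discovery by attribute walk, train/eval mode."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        seen = set()
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                    seen.add(id(v))
                    yield v

    def num_params(self, trainable_only: bool = False) -> int:
        total = sum(p.size for p in self.parameters())
        if not trainable_only:
            for m in self.modules():
                total += getattr(m, "frozen_param_count", 0)
        return total

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name->array mapping of all learned and running state."""
        out = {}
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    out[f"{i}.{k}"] = v.data
                elif isinstance(v, np.ndarray):
                    out[f"{i}.{k}"] = v
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                key = f"{i}.{k}"
                if key not in state:
                    continue
                if isinstance(v, Tensor) and v.requires_grad:
                    v.data = np.array(state[key], dtype=v.data.dtype)
                elif isinstance(v, np.ndarray):
                    m.__dict__[k] = np.array(state[key], dtype=v.dtype)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self.mods = list(mods)

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]

    def forward(self, *a, **k):  # pragma: no cover - container only
        raise RuntimeError("ModuleList is not callable")


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 padding: int | None = None, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = (k - 1) // 2 if padding is None else padding
        self.groups = groups
        fan_in = cin // groups * k * k
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Tensor(
            rng.normal(0.0, std, (cout, cin // groups, k, k)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding,
                        self.groups)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, unbiased = x.batchnorm_train(self.gamma, self.beta, self.eps)
            self.running_mean += self.momentum * (
                mu.astype(np.float32) - self.running_mean
            )
            self.running_var += self.momentum * (
                unbiased.astype(np.float32) - self.running_var
            )
            return out
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        shift = self.beta.data - self.running_mean * scale
        return x * scale.reshape(1, -1, 1, 1) + shift.reshape(1, -1, 1, 1)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class MaxPool2d(Module):
    def __init__(self, k: int, stride: int = 1, padding: int = 0):
        super().__init__()
        self.k, self.stride, self.padding = k, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool2d(self.k, self.stride, self.padding)


class Upsample2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.upsample2()


class ConvBNSiLU(Module):
    """CBS block: conv (no bias) + batch norm + SiLU."""

    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 groups: int = 1, act: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, groups=groups, bias=False,
                           rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = SiLU() if act else Identity()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


class DWConv(ConvBNSiLU):
    """Depthwise CBS (groups = channel count)."""

    def __init__(self, c: int, k: int = 3, stride: int = 1, act: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__(c, c, k, stride, groups=c, act=act, rng=rng)


class SGD:
    """Stochastic gradient descent with momentum and decoupled weight decay
    applied to conv kernels only (biases and norm affine terms excluded)."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.937,
                 weight_decay: float = 0.0005):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
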