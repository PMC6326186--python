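"""Layer and module abstractions over the autodiff core.

A :class:`Module` owns named parameters and composes into the network
graphs.  Convolutions use He-normal initialization from a seeded generator
so that training is reproducible bit-for-bit for a fixed seed and thread
count.
"""
from __future__ import annotations

import numpy as np

from .autograd import (Tensor, batch_norm, conv2d, max_pool2x2, relu,
                       sigmoid, upsample2x)

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ConvBnRelu", "MaxPool2x2",
           "Upsample2x", "Sequential"]


class Module:
    """Base class: parameter bookkeeping and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True, name=name)
        self._params[name] = t
        return t

    def parameters(self):
        for t in self._params.values():
            yield t
        for child in self._children.values():
            yield from child.parameters()

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.data.shape)) for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self):
        """Flat (name, array) list of parameters and buffers, for
        checkpointing."""
        out = []
        for prefix, m in self._walk():
            for n, p in m._params.items():
                out.append((f"{prefix}{n}", p.data))
            for n, b in getattr(m, "_buffers", {}).items():
                out.append((f"{prefix}{n}", b))
        return out

    def _walk(self, prefix=""):
        yield prefix, self
        for name, child in self._children.items():
            yield from child._walk(f"{prefix}{name}.")

    def load_state_arrays(self, named):
        table = dict(named)
        for prefix, m in self._walk():
            for n, p in m._params.items():
                p.data[...] = table[f"{prefix}{n}"]
            for n, b in getattr(m, "_buffers", {}).items():
                b[...] = table[f"{prefix}{n}"]


class Conv2d(Module):
    """'Same'-padded convolution with He-normal initialization."""

    def __init__(self, cin, cout, kernel, stride=1, dilation=1, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cin, self.cout, self.kernel = cin, cout, kernel
        self.stride, self.dilation = stride, dilation
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(cout, cin, kernel, kernel))
        self.weight = self.register("weight", w.astype(np.float32))
        self.bias = self.register("bias", np.zeros(cout, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.dilation)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = self.register("gamma", np.ones(c, np.float32))
        self.beta = self.register("beta", np.zeros(c, np.float32))
        self._buffers = {
            "running_mean": np.zeros(c, np.float32),
            "running_var": np.ones(c, np.float32),
        }
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm(x, self.gamma, self.beta,
                          self._buffers["running_mean"],
                          self._buffers["running_var"],
                          self.training, self.momentum, self.eps)


class ConvBnRelu(Module):
    """Conv -> BatchNorm -> ReLU, the standard unit of every network here."""

    def __init__(self, cin, cout, kernel, stride=1, dilation=1,
                 rng=None, activation=True):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride, dilation, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.activation = activation

    def forward(self, x):
        y = self.bn.forward(self.conv.forward(x))
        return relu(y) if self.activation else y


class MaxPool2x2(Module):
    def forward(self, x):
        return max_pool2x2(x)


class Upsample2x(Module):
    def forward(self, x):
        return upsample2x(x)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m.forward(x)
        return x
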