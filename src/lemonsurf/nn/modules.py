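"""Layer/module abstractions over the autodiff core (pytorch-like API)."""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix=""):
        for n, p in self._params.items():
            yield (prefix + n, p)
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix=""):
        for n, b in self._buffers.items():
            yield (prefix + n, b)
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode=True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        """Number of trainable scalar weights."""
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        sd = OrderedDict((n, p.data.copy()) for n, p in self.named_parameters())
        for n, b in self.named_buffers():
            sd[n] = np.array(b, copy=True)
        return sd

    def load_state_dict(self, sd):
        for n, p in self.named_parameters():
            p.data[...] = sd[n]
        for n, b in self.named_buffers():
            np.asarray(b)[...] = sd[n]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(self._list):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x

    def __getitem__(self, i):
        return self._list[i]


def _kaiming(shape, fan_in, rng):
    bound = float(np.sqrt(1.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


_INIT_RNG = np.random.default_rng(0)


def set_init_seed(seed: int):
    """Reseed the weight-initialisation stream (call before building a model)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


def init_uniform(shape, fan_in):
    """Fan-in scaled uniform init drawn from the shared init stream."""
    return _kaiming(shape, fan_in, _INIT_RNG)


class Conv2d(Module):
    def __init__(self, c1, c2, k=1, stride=1, padding=None, dilation=1, bias=False):
        super().__init__()
        if padding is None:
            padding = dilation * (k - 1) // 2
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = c1 * k * k
        self.weight = Parameter(init_uniform((c2, c1, k, k), fan_in))
        self.bias = Parameter(np.zeros(c2, dtype=np.float32)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, self.stride,
                        self.padding, self.dilation)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(c, dtype=np.float32))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x):
        return T.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training,
                            self.momentum, self.eps)


class SiLU(Module):
    def forward(self, x):
        return T.silu(x)


class Identity(Module):
    def forward(self, x):
        return x


class ConvBlock(Module):
    """Conv2d + BatchNorm + SiLU, the detector's standard convolution unit."""

    def __init__(self, c1, c2, k=1, stride=1, padding=None, dilation=1, act=True):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, stride, padding, dilation, bias=False)
        self.bn = BatchNorm2d(c2)
        self.act = act

    def forward(self, x):
        x = self.bn(self.conv(x))
        return T.silu(x) if self.act else x


class Upsample2x(Module):
    def forward(self, x):
        return T.upsample2x(x)


class MaxPool2d(Module):
    def __init__(self, kernel=5, stride=1, padding=2):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return T.max_pool2d(x, self.kernel, self.stride, self.padding)
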