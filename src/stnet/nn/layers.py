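"""Neural-network modules built on the autodiff primitives."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = [
    "Module", "Sequential", "Identity", "ReLU", "Sigmoid",
    "Conv2d", "ConvTranspose2d", "DeformableConv2d", "Linear",
    "BatchNorm2d", "MaxPool2d",
]


class Module:
    """Base class: tracks parameters, sub-modules and train/eval mode."""

    def __init__(self):
        self.training = True

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
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    yield v

    def named_parameters(self, prefix=""):
        for name, v in self.__dict__.items():
            if isinstance(v, Parameter):
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}.running_mean"] = m.running_mean.copy()
                state[f"{name}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float64).reshape(p.data.shape)
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"{name}.running_mean"], dtype=np.float64)
                m.running_var = np.asarray(state[f"{name}.running_var"], dtype=np.float64)

    def _named_modules(self, prefix=""):
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield f"{prefix}{name}", v
                yield from v._named_modules(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{prefix}{name}.{i}", item
                        yield from item._named_modules(f"{prefix}{name}.{i}.")


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, groups=1, bias=True, rng=None, zero_init=False):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"groups={groups} must divide channels ({in_channels}, {out_channels})"
            )
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        shape = (out_channels, in_channels // groups, k, k)
        w = np.zeros(shape) if zero_init else _he_init(rng, shape, fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.groups)


class ConvTranspose2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        shape = (in_channels, out_channels, k, k)
        self.weight = Parameter(_he_init(rng, shape, in_channels * k * k))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride,
                                  self.padding)


class DeformableConv2d(Module):
    """Deformable convolution with its offset layer.

    The offset field is produced by a standard convolution over the input.
    Its weights and biases start at zero, so at initialization the layer is
    exactly a standard convolution (zero-offset reduction).
    """

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        shape = (out_channels, in_channels, k, k)
        self.weight = Parameter(_he_init(rng, shape, in_channels * k * k))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.offset_conv = Conv2d(in_channels, 2 * k * k, kernel_size=k,
                                  stride=stride, padding=padding, bias=True,
                                  rng=rng, zero_init=True)
        self.stride, self.padding = stride, padding

    def forward(self, x):
        offsets = self.offset_conv(x)
        return F.deformable_conv2d(x, self.weight, offsets, self.bias,
                                   self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng=None,
                 zero_init=False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        shape = (in_features, out_features)
        w = np.zeros(shape) if zero_init else _he_init(rng, shape, in_features)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        C = x.data.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(C))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(C))
        else:
            mu = Tensor(self.running_mean.reshape(1, C, 1, 1))
            var = Tensor(self.running_var.reshape(1, C, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size
        self.padding = padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)
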