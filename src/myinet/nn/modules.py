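"""Layer/module abstraction over the autodiff engine.

Modules own parameters (Tensors with ``requires_grad=True``) and buffers
(plain arrays, e.g. batch-norm running statistics), can be nested through
attributes and lists, and serialise to flat name->array dictionaries.
Convolution weights use He fan-in initialisation drawn from an explicit
``numpy.random.Generator`` so that model construction is reproducible from a
single seed.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ReLU", "ReLU6", "MaxPool2d",
           "Sequential", "Identity"]


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ----------------------------------------------------------

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- mode ---------------------------------------------------------------

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- serialisation ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]} ...")
        for name, p in params.items():
            p.data = np.array(state[name], dtype=np.float64, copy=True)
        for name, b in buffers.items():
            b[...] = state[name]

    # -- call ---------------------------------------------------------------

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, *, stride: int = 1, padding: int = 0,
                 dilation: int = 1, groups: int = 1, bias: bool = False):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        k = int(kernel_size)
        fan_in = (in_channels // groups) * k * k
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(out_channels, in_channels // groups, k, k))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation,
                        groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, *, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return F.batch_norm2d(x, self.gamma, self.beta,
                              running_mean=self.running_mean,
                              running_var=self.running_var,
                              training=self.training, momentum=self.momentum,
                              eps=self.eps)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class ReLU6(Module):
    def forward(self, x):
        return F.relu6(x)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
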