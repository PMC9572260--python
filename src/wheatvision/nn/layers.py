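"""Neural-network modules built on the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ConvBNReLU", "Sequential"]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

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
            if isinstance(value, Parameter):
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[name + ".running_mean"] = m.running_mean.copy()
                state[name + ".running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float32).copy()
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(
                    state[name + ".running_mean"], dtype=np.float64
                ).copy()
                m.running_var = np.asarray(
                    state[name + ".running_var"], dtype=np.float64
                ).copy()
        return self

    def _named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for cname, child in self._children():
            yield from child._named_modules(prefix + cname + ".")


class Conv2d(Module):
    """Convolution with He-normal init; supports stride/dilation/groups."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        self.stride = stride
        self.dilation = dilation
        self.groups = groups
        fan_in = (in_ch // groups) * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_ch, in_ch // groups, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            dilation=self.dilation,
            groups=self.groups,
        )


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)

    def forward(self, x: Tensor) -> Tensor:
        return ad.batch_norm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class ConvBNReLU(Module):
    """conv → batchnorm → activation, the standard encoder building unit."""

    def __init__(
        self,
        in_ch,
        out_ch,
        kernel_size,
        rng,
        stride=1,
        dilation=1,
        groups=1,
        activation="relu",
    ):
        super().__init__()
        self.conv = Conv2d(
            in_ch,
            out_ch,
            kernel_size,
            rng,
            stride=stride,
            dilation=dilation,
            groups=groups,
            bias=False,
        )
        self.bn = BatchNorm2d(out_ch)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        if self.activation == "relu":
            return ad.relu(y)
        if self.activation == "relu6":
            return ad.relu6(y)
        return y


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
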