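"""Layers of the MBConv classification network.

Each layer owns its parameter Tensors (and, for batch norm, running-stat
buffers) and is callable on a Tensor. ``named_parameters`` /
``named_buffers`` walk the module tree to give the flat name -> array view
used by the optimizer and by weight archives.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class providing recursive parameter/buffer discovery."""

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
            yield from child.named_parameters(f"{prefix}{name}.")

    def named_buffers(self, prefix: str = ""):
        buffers = getattr(self, "_buffers", {})
        for name, value in buffers.items():
            yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(f"{prefix}{name}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Conv2d(Module):
    """2D convolution, no bias (always followed by batch norm here)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        fan_out = out_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_out)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)),
            requires_grad=True,
        )
        self.stride = stride

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ag.conv2d(x, self.weight, stride=self.stride)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        fan_out = kernel * kernel
        std = np.sqrt(2.0 / fan_out)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(channels, 1, kernel, kernel)),
            requires_grad=True,
        )
        self.stride = stride

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ag.depthwise_conv2d(x, self.weight, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-3):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=np.float32),
            "running_var": np.ones(channels, dtype=np.float32),
        }

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ag.batchnorm2d(
            x, self.gamma, self.beta,
            self._buffers["running_mean"], self._buffers["running_var"],
            training=training, momentum=self.momentum, eps=self.eps,
        )


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_dim)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(in_dim, out_dim)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ag.add(ag.matmul(x, self.weight), self.bias)


class ConvBNAct(Module):
    """Convolution -> batch norm -> swish (the stem and head pattern)."""

    def __init__(self, in_ch, out_ch, kernel, stride, rng):
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, rng)
        self.bn = BatchNorm2d(out_ch)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ag.swish(self.bn(self.conv(x), training))


class SqueezeExcite(Module):
    """Channel attention: pooled descriptor -> bottleneck -> sigmoid gate.

    The bottleneck width is se_ratio times the block's *input* channels,
    the convention of the reference MBConv design.
    """

    def __init__(self, channels: int, se_channels: int, rng):
        self.reduce = Linear(channels, se_channels, rng)
        self.expand = Linear(se_channels, channels, rng)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        s = ag.global_avg_pool(x)
        s = ag.swish(self.reduce(s))
        s = ag.sigmoid(self.expand(s))
        return ag.mul(x, ag.reshape(s, (n, c, 1, 1)))


class MBConvBlock(Module):
    """Mobile inverted bottleneck: 1x1 expand -> depthwise kxk ->
    squeeze-excitation -> 1x1 project, with a residual connection when the
    stride is 1 and channel counts match."""

    def __init__(self, in_ch: int, out_ch: int, expansion: int, kernel: int,
                 stride: int, rng: np.random.Generator,
                 se_ratio: float = 0.25, use_se: bool = True):
        mid = in_ch * expansion
        self.expand = None
        if expansion != 1:
            self.expand = Conv2d(in_ch, mid, 1, 1, rng)
            self.expand_bn = BatchNorm2d(mid)
        self.dw = DepthwiseConv2d(mid, kernel, stride, rng)
        self.dw_bn = BatchNorm2d(mid)
        self.se = None
        if use_se and se_ratio > 0:
            se_ch = max(1, int(in_ch * se_ratio))
            self.se = SqueezeExcite(mid, se_ch, rng)
        self.project = Conv2d(mid, out_ch, 1, 1, rng)
        self.project_bn = BatchNorm2d(out_ch)
        self.has_residual = stride == 1 and in_ch == out_ch

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        h = x
        if self.expand is not None:
            h = ag.swish(self.expand_bn(self.expand(h), training))
        h = ag.swish(self.dw_bn(self.dw(h), training))
        if self.se is not None:
            h = self.se(h, training)
        h = self.project_bn(self.project(h), training)
        if self.has_residual:
            h = ag.add(h, x)
        return h
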