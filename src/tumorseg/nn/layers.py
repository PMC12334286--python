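"""Layer modules built on the autodiff tensor ops.

Every layer knows three things: how to run forward (``__call__``), how many
parameters it owns split by trainability, and its analytic cost — output
shape and floating-point operations — for a given input shape.  FLOPs follow
the multiply-and-add-counted-separately convention (2 ops per MAC) for a
single forward pass.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class RngBox:
    """Shared random stream handed to stochastic layers (dropout)."""

    def __init__(self, seed=0):
        self.rng = np.random.default_rng(seed)

    def reseed(self, seed):
        self.rng = np.random.default_rng(seed)


class Module:
    """Base class: parameter/buffer registry with recursive traversal."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}

    def add_param(self, name, array) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        return t

    def add_buffer(self, name, array) -> np.ndarray:
        self._buffers[name] = array
        return array

    def add_module(self, name, module: "Module") -> "Module":
        self._modules[name] = module
        return module

    def parameters(self):
        for t in self._params.values():
            yield t
        for m in self._modules.values():
            yield from m.parameters()

    def buffers(self):
        for b in self._buffers.values():
            yield b
        for m in self._modules.values():
            yield from m.buffers()

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def freeze(self):
        """Mark every owned parameter non-trainable (e.g. a frozen encoder)."""
        for t in self.parameters():
            t.requires_grad = False
        return self

    def zero_grad(self):
        for t in self.parameters():
            t.zero_grad()

    def astype(self, dtype):
        for m in self.modules():
            for t in m._params.values():
                t.data = t.data.astype(dtype)
            for k in m._buffers:
                m._buffers[k] = m._buffers[k].astype(dtype)
        return self

    def state(self):
        """Deep copy of all parameters and buffers (checkpointing)."""
        snap = []
        for m in self.modules():
            snap.append(({k: v.data.copy() for k, v in m._params.items()},
                         {k: v.copy() for k, v in m._buffers.items()}))
        return snap

    def load_state(self, snap):
        for m, (ps, bs) in zip(self.modules(), snap):
            for k, v in ps.items():
                m._params[k].data = v.copy()
            for k, v in bs.items():
                m._buffers[k] = v.copy()

    # cost model -- subclasses with parameters/compute override
    def cost(self, in_shape):
        """Return ``(out_shape, flops)`` for spatial input shape (H, W, C)."""
        return in_shape, 0


def he_normal(rng, shape, fan_in, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2D(Module):
    """Same-padded stride-1 convolution with bias."""

    def __init__(self, cin, cout, kernel, rng, dtype=np.float32):
        super().__init__()
        self.cin, self.cout, self.kernel = cin, cout, kernel
        fan_in = kernel * kernel * cin
        self.w = self.add_param("w", he_normal(rng, (kernel, kernel, cin, cout), fan_in, dtype))
        self.b = self.add_param("b", np.zeros(cout, dtype=dtype))

    def __call__(self, x, training=False):
        return T.conv2d(x, self.w, self.b)

    def cost(self, in_shape):
        h, w, _ = in_shape
        flops = 2 * h * w * self.kernel ** 2 * self.cin * self.cout + h * w * self.cout
        return (h, w, self.cout), flops


class DepthwiseConv2D(Module):
    def __init__(self, channels, kernel, rng, dtype=np.float32):
        super().__init__()
        self.channels, self.kernel = channels, kernel
        fan_in = kernel * kernel
        self.w = self.add_param("w", he_normal(rng, (kernel, kernel, channels), fan_in, dtype))
        self.b = self.add_param("b", np.zeros(channels, dtype=dtype))

    def __call__(self, x, training=False):
        return T.depthwise_conv2d(x, self.w, self.b)

    def cost(self, in_shape):
        h, w, c = in_shape
        return (h, w, c), 2 * h * w * self.kernel ** 2 * c + h * w * c


class ConvTranspose2D(Module):
    """2x2 stride-2 learnable upsampling."""

    def __init__(self, cin, cout, rng, dtype=np.float32):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.w = self.add_param("w", he_normal(rng, (2, 2, cin, cout), cin, dtype))
        self.b = self.add_param("b", np.zeros(cout, dtype=dtype))

    def __call__(self, x, training=False):
        return T.conv2d_transpose(x, self.w, self.b)

    def cost(self, in_shape):
        h, w, _ = in_shape
        return (2 * h, 2 * w, self.cout), 2 * 4 * h * w * self.cin * self.cout + 4 * h * w * self.cout


class DepthwiseConvTranspose2D(Module):
    def __init__(self, channels, rng, dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.w = self.add_param("w", he_normal(rng, (2, 2, channels), 1, dtype))
        self.b = self.add_param("b", np.zeros(channels, dtype=dtype))

    def __call__(self, x, training=False):
        return T.depthwise_conv2d_transpose(x, self.w, self.b)

    def cost(self, in_shape):
        h, w, c = in_shape
        return (2 * h, 2 * w, c), 2 * 4 * h * w * c + 4 * h * w * c


class BatchNorm2D(Module):
    """Batch normalization over (N, H, W); moving statistics are buffers."""

    def __init__(self, channels, momentum=0.99, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = self.add_param("gamma", np.ones(channels, dtype=dtype))
        self.beta = self.add_param("beta", np.zeros(channels, dtype=dtype))
        self.add_buffer("moving_mean", np.zeros(channels, dtype=dtype))
        self.add_buffer("moving_var", np.ones(channels, dtype=dtype))

    def __call__(self, x, training=False):
        gamma, beta = self.gamma, self.beta
        if training:
            mu = x.data.mean(axis=(0, 1, 2))
            var = x.data.var(axis=(0, 1, 2))
            m = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]
            mom = self.momentum
            self._buffers["moving_mean"] = (mom * self._buffers["moving_mean"] + (1 - mom) * mu).astype(x.dtype)
            self._buffers["moving_var"] = (mom * self._buffers["moving_var"] + (1 - mom) * var).astype(x.dtype)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x.data - mu) * inv
            out_data = gamma.data * xhat + beta.data

            def backward(g):
                if gamma.requires_grad:
                    gamma._accumulate((g * xhat).sum(axis=(0, 1, 2)))
                if beta.requires_grad:
                    beta._accumulate(g.sum(axis=(0, 1, 2)))
                if x.requires_grad or x._parents:
                    sg = g.sum(axis=(0, 1, 2))
                    sgx = (g * xhat).sum(axis=(0, 1, 2))
                    dx = (gamma.data * inv / m) * (m * g - sg - xhat * sgx)
                    x._accumulate(dx.astype(x.dtype))

            parents = (x, gamma, beta)
        else:
            inv = 1.0 / np.sqrt(self._buffers["moving_var"] + self.eps)
            xhat = (x.data - self._buffers["moving_mean"]) * inv
            out_data = gamma.data * xhat + beta.data

            def backward(g):
                if gamma.requires_grad:
                    gamma._accumulate((g * xhat).sum(axis=(0, 1, 2)))
                if beta.requires_grad:
                    beta._accumulate(g.sum(axis=(0, 1, 2)))
                if x.requires_grad or x._parents:
                    x._accumulate((g * gamma.data * inv).astype(x.dtype))

            parents = (x, gamma, beta)
        if any(p.requires_grad or p._parents for p in parents):
            return Tensor(out_data.astype(x.dtype), parents=parents, backward=backward)
        return Tensor(out_data.astype(x.dtype))

    def cost(self, in_shape):
        h, w, c = in_shape
        return (h, w, c), 4 * h * w * c


class Dense(Module):
    def __init__(self, cin, cout, rng, dtype=np.float32, zero_bias=True):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.w = self.add_param("w", he_normal(rng, (cin, cout), cin, dtype))
        self.b = self.add_param("b", np.zeros(cout, dtype=dtype))

    def __call__(self, x, training=False):
        return T.add(T.matmul(x, self.w), self.b)

    def cost(self, in_shape):
        return (self.cout,), 2 * self.cin * self.cout + self.cout


class Dropout(Module):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rngbox: RngBox):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rngbox = rngbox

    def __call__(self, x, training=False):
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rngbox.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return T.mul(x, Tensor(mask))


class MaxPool2D(Module):
    def __call__(self, x, training=False):
        return T.maxpool2x2(x)

    def cost(self, in_shape):
        h, w, c = in_shape
        return (h // 2, w // 2, c), 3 * (h // 2) * (w // 2) * c


def count_params(module: Module):
    """(trainable, non_trainable) parameter counts.

    Non-trainable = frozen weights plus moving statistics buffers.
    """
    trainable = 0
    frozen = 0
    for t in module.parameters():
        if t.requires_grad:
            trainable += t.data.size
        else:
            frozen += t.data.size
    buffered = sum(b.size for b in module.buffers())
    return trainable, frozen + buffered
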