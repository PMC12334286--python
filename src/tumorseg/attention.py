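"""Convolutional Block Attention Module (CBAM) and separable-conv units.

CBAM refines a feature map in two sequential stages: channel attention
(a shared two-layer bottleneck MLP over average- and max-pooled channel
descriptors, sigmoid-gated) followed by spatial attention (a k x k
convolution over the channel-wise average and max maps, sigmoid-gated).
The separable convolution unit — depthwise k x k, pointwise 1 x 1, batch
normalization, ReLU — is the workhorse of the lightweight decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor


@dataclass(frozen=True)
class CBAMConfig:
    """Attention hyperparameters.

    The reduced MLP width is ``max(1, C // reduction_ratio)``.  With
    ``use_separable_convs`` the spatial convolution is depthwise-separable,
    mirroring the separable design of the rest of the decoder.
    """

    reduction_ratio: int = 16
    spatial_kernel: int = 7
    use_separable_convs: bool = True

    def validate(self):
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be a positive integer")
        if self.spatial_kernel < 1 or self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be an odd positive integer")
        return self


def _ensure_batched(features):
    arr = np.asarray(features)
    if arr.ndim == 3:
        return arr[None], True
    return arr, False


class ChannelAttention(nn.Module):
    """Per-channel sigmoid gates from pooled channel descriptors."""

    def __init__(self, channels, config: CBAMConfig, rng, dtype=np.float32):
        super().__init__()
        config.validate()
        self.channels = channels
        reduced = max(1, channels // config.reduction_ratio)
        self.fc1 = self.add_module("fc1", nn.Dense(channels, reduced, rng, dtype))
        self.fc2 = self.add_module("fc2", nn.Dense(reduced, channels, rng, dtype))
        self.reduced = reduced

    def weights(self, x: Tensor) -> Tensor:
        """(N, C) gate values, each strictly inside (0, 1)."""
        avg = T.reshape(T.mean_axes(x, (1, 2)), (x.shape[0], x.shape[3]))
        mx = T.reshape(T.max_axes(x, (1, 2)), (x.shape[0], x.shape[3]))
        shared = lambda d: self.fc2(T.relu(self.fc1(d)))
        return T.sigmoid(T.add(shared(avg), shared(mx)))

    def __call__(self, x: Tensor, training=False) -> Tensor:
        w = self.weights(x)
        return T.mul(x, T.reshape(w, (x.shape[0], 1, 1, x.shape[3])))

    def cost(self, in_shape):
        h, w, c = in_shape
        mlp = 2 * (2 * c * self.reduced + self.reduced + 2 * self.reduced * c + c)
        return (h, w, c), 4 * h * w * c + mlp + 2 * c + h * w * c


class SpatialAttention(nn.Module):
    """Per-pixel sigmoid gates from channel-pooled maps."""

    def __init__(self, config: CBAMConfig, rng, dtype=np.float32):
        super().__init__()
        config.validate()
        self.config = config
        k = config.spatial_kernel
        if config.use_separable_convs:
            self.dw = self.add_module("dw", nn.DepthwiseConv2D(2, k, rng, dtype))
            self.pw = self.add_module("pw", nn.Conv2D(2, 1, 1, rng, dtype))
            self._conv = lambda z: self.pw(self.dw(z))
        else:
            self.conv = self.add_module("conv", nn.Conv2D(2, 1, k, rng, dtype))
            self._conv = self.conv

    def weights(self, x: Tensor) -> Tensor:
        """(N, H, W, 1) gate values, each strictly inside (0, 1)."""
        avg = T.mean_axes(x, (3,))
        mx = T.max_axes(x, (3,))
        pooled = T.concat([avg, mx], axis=3)
        return T.sigmoid(self._conv(pooled))

    def __call__(self, x: Tensor, training=False) -> Tensor:
        return T.mul(x, self.weights(x))

    def cost(self, in_shape):
        h, w, c = in_shape
        k = self.config.spatial_kernel
        if self.config.use_separable_convs:
            conv = 2 * h * w * k * k * 2 + 2 * h * w * 2 * 1 + 3 * h * w
        else:
            conv = 2 * h * w * k * k * 2 * 1 + h * w
        return (h, w, c), 2 * h * w * c + conv + h * w + h * w * c


class CBAM(nn.Module):
    """Sequential channel-then-spatial attention refinement."""

    def __init__(self, channels, config: CBAMConfig, rng, dtype=np.float32):
        super().__init__()
        self.channel = self.add_module("channel", ChannelAttention(channels, config, rng, dtype))
        self.spatial = self.add_module("spatial", SpatialAttention(config, rng, dtype))

    def __call__(self, x: Tensor, training=False) -> Tensor:
        return self.spatial(self.channel(x))

    def cost(self, in_shape):
        s1, f1 = self.channel.cost(in_shape)
        s2, f2 = self.spatial.cost(s1)
        return s2, f1 + f2


class SeparableConvUnit(nn.Module):
    """Depthwise k x k -> pointwise 1 x 1 -> batch norm -> ReLU."""

    def __init__(self, cin, cout, kernel, rng, dtype=np.float32, bn_momentum=0.9):
        super().__init__()
        self.dw = self.add_module("dw", nn.DepthwiseConv2D(cin, kernel, rng, dtype))
        self.pw = self.add_module("pw", nn.Conv2D(cin, cout, 1, rng, dtype))
        self.bn = self.add_module("bn", nn.BatchNorm2D(cout, momentum=bn_momentum, dtype=dtype))

    def __call__(self, x: Tensor, training=False) -> Tensor:
        return T.relu(self.bn(self.pw(self.dw(x)), training=training))

    def cost(self, in_shape):
        s, f = self.dw.cost(in_shape)
        s, f2 = self.pw.cost(s)
        s, f3 = self.bn.cost(s)
        h, w, c = s
        return s, f + f2 + f3 + h * w * c


class SeparableConvTranspose2D(nn.Module):
    """Depthwise 2x2 stride-2 transposed conv followed by a pointwise mix."""

    def __init__(self, cin, cout, rng, dtype=np.float32):
        super().__init__()
        self.dw = self.add_module("dw", nn.DepthwiseConvTranspose2D(cin, rng, dtype))
        self.pw = self.add_module("pw", nn.Conv2D(cin, cout, 1, rng, dtype))

    def __call__(self, x: Tensor, training=False) -> Tensor:
        return self.pw(self.dw(x))

    def cost(self, in_shape):
        s, f = self.dw.cost(in_shape)
        s, f2 = self.pw.cost(s)
        return s, f + f2


# -- functional wrappers (single H x W x C grids) --------------------------

def channel_attention(features, config: CBAMConfig, seed: int = 0) -> np.ndarray:
    """Channel gate vector (length C) for one feature grid."""
    arr, _ = _ensure_batched(features)
    block = ChannelAttention(arr.shape[3], config, np.random.default_rng(seed), arr.dtype)
    return block.weights(Tensor(arr)).data[0]


def spatial_attention(features, config: CBAMConfig, seed: int = 0) -> np.ndarray:
    """Spatial gate map (H x W) for one feature grid."""
    arr, _ = _ensure_batched(features)
    block = SpatialAttention(config, np.random.default_rng(seed), arr.dtype)
    return block.weights(Tensor(arr)).data[0, :, :, 0]


def cbam(features, config: CBAMConfig, seed: int = 0) -> np.ndarray:
    """CBAM-refined copy of one feature grid (same shape)."""
    arr, _ = _ensure_batched(features)
    block = CBAM(arr.shape[3], config, np.random.default_rng(seed), arr.dtype)
    return block(Tensor(arr)).data[0]
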