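"""Segmentation network builders and parameter/FLOP accounting.

Three architectures are provided:

* ``unet`` — the classic symmetric U-Net (encoder 64-128-256-512, bottleneck
  1024, transposed-conv decoder with skip concatenations);
* ``vgg19_unet`` — a VGG19 convolutional encoder with a standard-conv,
  batch-normalized decoder;
* ``proposed`` — the VGG19 encoder (trainable, dropout after each block) with
  a lightweight decoder: depthwise-separable transposed-conv upsampling, skip
  concatenation, CBAM refinement, and a run of batch-normalized separable
  conv units per stage, ending in a 1 x 1 sigmoid head.

The default proposed configuration (decoder widths 128/64/32/16, six
separable units per stage, CBAM reduction ratio 16) is chosen so that the
parameter census lands on the published complexity figures: 2880
non-trainable parameters (two moving statistics per batch-normalized
channel) and a trainable count that rounds to 20.4 million.

FLOPs are analytic: multiply and add counted separately (2 ops per MAC) for
one forward pass at the configured input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor
from .attention import CBAM, CBAMConfig, SeparableConvTranspose2D, SeparableConvUnit
from .sample import MRISample

_VGG19_BLOCKS = ((2, 64), (2, 128), (4, 256), (4, 512), (4, 512))


@dataclass(frozen=True)
class ModelConfig:
    architecture: str = "proposed"
    input_height: int = 256
    input_width: int = 256
    input_channels: int = 3
    decoder_widths: tuple[int, ...] | None = None
    convs_per_decoder_stage: int = 6
    dropout_rate: float = 0.2
    cbam: CBAMConfig = field(default_factory=CBAMConfig)
    encoder_trainable: bool = True
    width_multiplier: float = 1.0
    dtype: str = "float32"
    # initialization: the sigmoid head starts at the foreground prior
    # (bias = logit(prior)), and the decoder's convolutions start at a
    # reduced He gain -- batch normalization makes the forward pass invariant
    # to that scale while small-step optimizers adapt small weights faster.
    foreground_prior: float = 0.1
    decoder_init_gain: float = 0.05

    def validate(self):
        if self.architecture not in ("unet", "vgg19_unet", "proposed"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.input_height % 16 or self.input_width % 16:
            raise ValueError("input size must be divisible by 16 (four 2x2 poolings)")
        if self.input_height <= 0 or self.input_width <= 0 or self.input_channels <= 0:
            raise ValueError("input dimensions must be positive")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if self.convs_per_decoder_stage < 1:
            raise ValueError("convs_per_decoder_stage must be >= 1")
        if not 0.0 < self.foreground_prior < 1.0:
            raise ValueError("foreground_prior must lie in (0, 1)")
        if self.decoder_init_gain <= 0:
            raise ValueError("decoder_init_gain must be positive")
        widths = self.resolved_decoder_widths()
        if len(widths) != 4:
            raise ValueError("decoder_widths must list one width per upsampling stage (4)")
        if any(a <= b for a, b in zip(widths, widths[1:])):
            raise ValueError("decoder_widths must be strictly decreasing")
        self.cbam.validate()
        return self

    def resolved_decoder_widths(self):
        if self.decoder_widths is not None:
            return tuple(self.decoder_widths)
        if self.architecture == "proposed":
            return (128, 64, 32, 16)
        return (512, 256, 128, 64)


@dataclass(frozen=True)
class ParameterCensus:
    trainable: int
    non_trainable: int
    flops: int

    @property
    def total(self):
        return self.trainable + self.non_trainable


def _scaled(width, multiplier):
    return max(1, int(round(width * multiplier)))


def _init_head(head, config):
    head.b.data[:] = np.log(config.foreground_prior / (1.0 - config.foreground_prior))


class _Tape:
    """Accumulates output shapes, FLOPs and a layer table during build."""

    def __init__(self, shape):
        self.shape = shape
        self.flops = 0
        self.rows = []

    def through(self, layer, name):
        out, f = layer.cost(self.shape)
        self.flops += f
        trainable, non_trainable = nn.count_params(layer)
        self.rows.append({"layer": name, "output_shape": out,
                          "params": trainable + non_trainable})
        self.shape = out
        return out

    def concat(self, channels, name):
        h, w, c = self.shape
        self.shape = (h, w, c + channels)
        self.rows.append({"layer": name, "output_shape": self.shape, "params": 0})
        return self.shape


class SegmentationNetwork(nn.Module):
    """Base class: a built graph with a forward pass, an input contract,
    an analytic FLOP count, and a layer summary table."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        self.input_shape = (config.input_height, config.input_width, config.input_channels)
        self.rngbox = nn.RngBox(0)
        self.flops = 0
        self.summary_rows = []

    def forward(self, x: Tensor, training=False) -> Tensor:
        raise NotImplementedError

    def predict(self, images) -> np.ndarray:
        """Probability maps (N, H, W) for a batch of (N, H, W, C) images."""
        arr = np.asarray(images, dtype=self._dtype())
        if arr.ndim == 3:
            arr = arr[None]
        if arr.shape[1:] != self.input_shape:
            raise ValueError(f"input shape {arr.shape[1:]} does not match "
                             f"network input {self.input_shape}")
        out = self.forward(Tensor(arr), training=False)
        return out.data[..., 0]

    def reseed(self, seed):
        self.rngbox.reseed(seed)

    def _dtype(self):
        return next(iter(self.parameters())).data.dtype


class VGG19Encoder(nn.Module):
    """The 16-convolution VGG19 feature stack with per-block skip tap-offs."""

    def __init__(self, cin, rng, dtype, multiplier=1.0, dropout_rate=0.0, rngbox=None):
        super().__init__()
        self.convs_per_block = []
        self.block_widths = []
        self.dropout = nn.Dropout(dropout_rate, rngbox) if dropout_rate > 0 else None
        if self.dropout is not None:
            self.add_module("dropout", self.dropout)
        c = cin
        for bi, (nconvs, width) in enumerate(_VGG19_BLOCKS, start=1):
            width = _scaled(width, multiplier)
            self.block_widths.append(width)
            self.convs_per_block.append(nconvs)
            for ci in range(1, nconvs + 1):
                self.add_module(f"block{bi}_conv{ci}", nn.Conv2D(c, width, 3, rng, dtype))
                c = width
        self.pool = nn.MaxPool2D()

    def __call__(self, x: Tensor, training=False):
        """Returns (skips from blocks 1-4, bridge = block-5 output)."""
        skips = []
        for bi, nconvs in enumerate(self.convs_per_block, start=1):
            for ci in range(1, nconvs + 1):
                x = T.relu(self._modules[f"block{bi}_conv{ci}"](x))
            if self.dropout is not None:
                x = self.dropout(x, training=training)
            if bi < 5:
                skips.append(x)
                x = self.pool(x)
        return skips, x

    def trace(self, tape: _Tape):
        skip_shapes = []
        for bi, nconvs in enumerate(self.convs_per_block, start=1):
            for ci in range(1, nconvs + 1):
                name = f"block{bi}_conv{ci}"
                tape.through(self._modules[name], name)
            if bi < 5:
                skip_shapes.append(tape.shape)
                tape.through(self.pool, f"pool{bi}")
        return skip_shapes, tape.shape


class UNet(SegmentationNetwork):
    """Classic symmetric U-Net with a sigmoid pixel-probability head."""

    def __init__(self, config: ModelConfig, seed=0):
        super().__init__(config)
        rng = np.random.default_rng(seed)
        dtype = np.dtype(config.dtype)
        m = config.width_multiplier
        widths = [_scaled(w, m) for w in (64, 128, 256, 512)]
        bottleneck = _scaled(1024, m)
        tape = _Tape(self.input_shape)
        self.pool = nn.MaxPool2D()

        c = config.input_channels
        skip_shapes = []
        for i, w in enumerate(widths, start=1):
            self.add_module(f"enc{i}_conv1", nn.Conv2D(c, w, 3, rng, dtype))
            self.add_module(f"enc{i}_conv2", nn.Conv2D(w, w, 3, rng, dtype))
            tape.through(self._modules[f"enc{i}_conv1"], f"enc{i}_conv1")
            tape.through(self._modules[f"enc{i}_conv2"], f"enc{i}_conv2")
            skip_shapes.append(tape.shape)
            tape.through(self.pool, f"pool{i}")
            c = w
        self.add_module("bottleneck_conv1", nn.Conv2D(c, bottleneck, 3, rng, dtype))
        self.add_module("bottleneck_conv2", nn.Conv2D(bottleneck, bottleneck, 3, rng, dtype))
        tape.through(self._modules["bottleneck_conv1"], "bottleneck_conv1")
        tape.through(self._modules["bottleneck_conv2"], "bottleneck_conv2")

        c = bottleneck
        for i, w in enumerate(reversed(widths), start=1):
            self.add_module(f"dec{i}_up", nn.ConvTranspose2D(c, w, rng, dtype))
            tape.through(self._modules[f"dec{i}_up"], f"dec{i}_up")
            tape.concat(w, f"dec{i}_concat")
            self.add_module(f"dec{i}_conv1", nn.Conv2D(2 * w, w, 3, rng, dtype))
            self.add_module(f"dec{i}_conv2", nn.Conv2D(w, w, 3, rng, dtype))
            tape.through(self._modules[f"dec{i}_conv1"], f"dec{i}_conv1")
            tape.through(self._modules[f"dec{i}_conv2"], f"dec{i}_conv2")
            c = w
        self.add_module("head", nn.Conv2D(c, 1, 1, rng, dtype))
        _init_head(self._modules["head"], config)
        tape.through(self._modules["head"], "head")
        self.flops = tape.flops
        self.summary_rows = tape.rows

    def forward(self, x: Tensor, training=False) -> Tensor:
        skips = []
        for i in range(1, 5):
            x = T.relu(self._modules[f"enc{i}_conv1"](x))
            x = T.relu(self._modules[f"enc{i}_conv2"](x))
            skips.append(x)
            x = self.pool(x)
        x = T.relu(self._modules["bottleneck_conv1"](x))
        x = T.relu(self._modules["bottleneck_conv2"](x))
        for i in range(1, 5):
            x = self._modules[f"dec{i}_up"](x)
            x = T.concat([x, skips[4 - i]], axis=3)
            x = T.relu(self._modules[f"dec{i}_conv1"](x))
            x = T.relu(self._modules[f"dec{i}_conv2"](x))
        return T.sigmoid(self._modules["head"](x))


class VGG19UNet(SegmentationNetwork):
    """VGG19 encoder with a standard-convolution, batch-normalized decoder."""

    def __init__(self, config: ModelConfig, seed=0):
        super().__init__(config)
        rng = np.random.default_rng(seed)
        dtype = np.dtype(config.dtype)
        m = config.width_multiplier
        self.encoder = self.add_module(
            "encoder",
            VGG19Encoder(config.input_channels, rng, dtype, multiplier=m))
        tape = _Tape(self.input_shape)
        skip_shapes, bridge_shape = self.encoder.trace(tape)

        # width_multiplier scales the encoder trunk; decoder widths are set
        # directly through the config
        widths = list(config.resolved_decoder_widths())
        c = bridge_shape[2]
        for i, w in enumerate(widths, start=1):
            skip_c = skip_shapes[4 - i][2]
            self.add_module(f"dec{i}_up", nn.ConvTranspose2D(c, w, rng, dtype))
            tape.through(self._modules[f"dec{i}_up"], f"dec{i}_up")
            tape.concat(skip_c, f"dec{i}_concat")
            self.add_module(f"dec{i}_conv1", nn.Conv2D(w + skip_c, w, 3, rng, dtype))
            self.add_module(f"dec{i}_bn1", nn.BatchNorm2D(w, momentum=0.9, dtype=dtype))
            self.add_module(f"dec{i}_conv2", nn.Conv2D(w, w, 3, rng, dtype))
            self.add_module(f"dec{i}_bn2", nn.BatchNorm2D(w, momentum=0.9, dtype=dtype))
            for part in ("conv1", "bn1", "conv2", "bn2"):
                tape.through(self._modules[f"dec{i}_{part}"], f"dec{i}_{part}")
            c = w
        self.add_module("head", nn.Conv2D(c, 1, 1, rng, dtype))
        _init_head(self._modules["head"], config)
        tape.through(self._modules["head"], "head")
        if not config.encoder_trainable:
            self.encoder.freeze()
        self.flops = tape.flops
        self.summary_rows = tape.rows

    def forward(self, x: Tensor, training=False) -> Tensor:
        skips, x = self.encoder(x, training=training)
        for i in range(1, 5):
            x = self._modules[f"dec{i}_up"](x)
            x = T.concat([x, skips[4 - i]], axis=3)
            x = T.relu(self._modules[f"dec{i}_bn1"](self._modules[f"dec{i}_conv1"](x), training=training))
            x = T.relu(self._modules[f"dec{i}_bn2"](self._modules[f"dec{i}_conv2"](x), training=training))
        return T.sigmoid(self._modules["head"](x))


class ProposedUNet(SegmentationNetwork):
    """VGG19 encoder + CBAM separable-convolution decoder (the lightweight model)."""

    def __init__(self, config: ModelConfig, seed=0):
        super().__init__(config)
        rng = np.random.default_rng(seed)
        dtype = np.dtype(config.dtype)
        m = config.width_multiplier
        self.encoder = self.add_module(
            "encoder",
            VGG19Encoder(config.input_channels, rng, dtype, multiplier=m,
                         dropout_rate=config.dropout_rate, rngbox=self.rngbox))
        tape = _Tape(self.input_shape)
        skip_shapes, bridge_shape = self.encoder.trace(tape)

        # width_multiplier scales the encoder trunk; decoder widths are set
        # directly through the config
        widths = list(config.resolved_decoder_widths())
        self.n_units = config.convs_per_decoder_stage
        c = bridge_shape[2]  # bottleneck: pass-through of the block-5 features
        for i, w in enumerate(widths, start=1):
            skip_c = skip_shapes[4 - i][2]
            self.add_module(f"dec{i}_up", SeparableConvTranspose2D(c, w, rng, dtype))
            tape.through(self._modules[f"dec{i}_up"], f"dec{i}_up")
            tape.concat(skip_c, f"dec{i}_concat")
            cat = w + skip_c
            self.add_module(f"dec{i}_cbam", CBAM(cat, config.cbam, rng, dtype))
            tape.through(self._modules[f"dec{i}_cbam"], f"dec{i}_cbam")
            uc = cat
            for j in range(1, self.n_units + 1):
                self.add_module(f"dec{i}_unit{j}",
                                SeparableConvUnit(uc, w, 3, rng, dtype))
                tape.through(self._modules[f"dec{i}_unit{j}"], f"dec{i}_unit{j}")
                uc = w
            c = w
        self.add_module("head", nn.Conv2D(c, 1, 1, rng, dtype))
        _init_head(self._modules["head"], config)
        tape.through(self._modules["head"], "head")
        if not config.encoder_trainable:
            self.encoder.freeze()
        if config.decoder_init_gain != 1.0:
            for name, mod in self._modules.items():
                if name.startswith("dec"):
                    for sub in mod.modules():
                        if "w" in sub._params:
                            sub._params["w"].data *= config.decoder_init_gain
        self.flops = tape.flops
        self.summary_rows = tape.rows

    def forward(self, x: Tensor, training=False) -> Tensor:
        skips, x = self.encoder(x, training=training)
        for i in range(1, 5):
            x = self._modules[f"dec{i}_up"](x)
            x = T.concat([x, skips[4 - i]], axis=3)
            x = self._modules[f"dec{i}_cbam"](x)
            for j in range(1, self.n_units + 1):
                x = self._modules[f"dec{i}_unit{j}"](x, training=training)
        return T.sigmoid(self._modules["head"](x))


# ---------------------------------------------------------------------------
# public builders and accounting
# ---------------------------------------------------------------------------

def build_unet(config: ModelConfig | None = None, seed: int = 0) -> UNet:
    config = config or ModelConfig(architecture="unet")
    config.validate()
    if config.architecture != "unet":
        raise ValueError("config.architecture must be 'unet'")
    return UNet(config, seed)


def build_vgg19_unet(config: ModelConfig | None = None, seed: int = 0) -> VGG19UNet:
    config = config or ModelConfig(architecture="vgg19_unet")
    config.validate()
    if config.architecture != "vgg19_unet":
        raise ValueError("config.architecture must be 'vgg19_unet'")
    return VGG19UNet(config, seed)


def build_proposed(config: ModelConfig | None = None, seed: int = 0) -> ProposedUNet:
    config = config or ModelConfig(architecture="proposed")
    config.validate()
    if config.architecture != "proposed":
        raise ValueError("config.architecture must be 'proposed'")
    return ProposedUNet(config, seed)


def build_model(config: ModelConfig, seed: int = 0) -> SegmentationNetwork:
    builder = {"unet": build_unet, "vgg19_unet": build_vgg19_unet,
               "proposed": build_proposed}[config.validate().architecture]
    return builder(config, seed)


def count_parameters(network: SegmentationNetwork) -> ParameterCensus:
    """Exact integer parameter counts partitioned by trainability, plus the
    analytic forward-pass FLOP count at the configured input size."""
    trainable, non_trainable = nn.count_params(network)
    return ParameterCensus(trainable=trainable, non_trainable=non_trainable,
                           flops=network.flops)


def predict_mask(network: SegmentationNetwork, sample: MRISample,
                 threshold: float = 0.5) -> np.ndarray:
    """Binarize the network's probability map at ``threshold``."""
    if sample.image.shape != network.input_shape:
        raise ValueError(f"sample shape {sample.image.shape} does not match "
                         f"network input {network.input_shape}")
    probs = network.predict(sample.image[None])[0]
    return (probs >= threshold).astype(np.uint8)


def save_weights(network: SegmentationNetwork, path):
    """Checkpoint all parameters and buffers to a .npz file."""
    arrays = {}
    for i, (ps, bs) in enumerate(network.state()):
        for k, v in ps.items():
            arrays[f"m{i}.p.{k}"] = v
        for k, v in bs.items():
            arrays[f"m{i}.b.{k}"] = v
    np.savez(path, **arrays)


def load_weights(network: SegmentationNetwork, path):
    """Restore a checkpoint written by :func:`save_weights` into a network
    built with the same configuration."""
    with np.load(path) as data:
        snap = []
        for i, (ps, bs) in enumerate(network.state()):
            snap.append(({k: data[f"m{i}.p.{k}"] for k in ps},
                         {k: data[f"m{i}.b.{k}"] for k in bs}))
    network.load_state(snap)
    return network


def summary_table(network: SegmentationNetwork):
    """Layer table (name, output shape, parameter count) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(network.summary_rows)
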