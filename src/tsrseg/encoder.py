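"""Convolutional feature extractors with output stride 16.

The main backbone is a MobileNetV2-style network truncated after its 16th
inverted-residual bottleneck, with that bottleneck's final projection
convolution removed. In the standard layer counting the 14th bottleneck
halves resolution a fifth time; to honour the contract that the input is
reduced by a factor of exactly 16 (not 32), that bottleneck's stride is
set to 1 here. The feature dimensionality at the cut is whatever the
expansion arithmetic yields at width multiplier alpha (6 x the width of
the 160-channel stage); it is reported, not hard-coded.

A small generic encoder with the same interface is provided for
desk-scale experiments where the full backbone would be needlessly large.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import BatchNorm2d, Conv2d, DepthwiseConv2d, Module, Tensor
from .nn import add as t_add
from .nn import relu, relu6

# (expansion t, channels c, repeats n, stride s); stride of the 160 stage
# forced to 1 to keep output stride 16.
_MOBILENET_SETTINGS = (
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 1),
)
_N_BOTTLENECKS = 16  # truncation point


def make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


def truncated_channels(alpha: float) -> int:
    """Feature channels at the truncation cut (projection conv removed)."""
    return 6 * make_divisible(160 * alpha)


@dataclass(frozen=True)
class EncoderConfig:
    alpha: float = 1.0
    patch_size: int = 512
    output_stride: int = 16
    init: str = "random"            # "random" | "pretrained"
    weights_path: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.output_stride != 16:
            raise ValueError("output_stride is fixed at 16")
        if self.patch_size % 16 != 0:
            raise ValueError(f"patch_size {self.patch_size} not divisible "
                             "by 16")
        if self.init not in ("random", "pretrained"):
            raise ValueError("init must be 'random' or 'pretrained'")
        if self.init == "pretrained" and not self.weights_path:
            raise ValueError("pretrained init requires weights_path")


class _ConvBNReLU6(Module):
    def __init__(self, c_in, c_out, k, stride, rng):
        self.conv = Conv2d(c_in, c_out, k, stride=stride, bias=False,
                           rng=rng)
        self.bn = BatchNorm2d(c_out)

    def __call__(self, x, training):
        return relu6(self.bn(self.conv(x), training))


class _InvertedResidual(Module):
    def __init__(self, c_in, c_out, stride, expand, rng,
                 keep_projection=True):
        hidden = c_in * expand
        self.expand_conv = (_ConvBNReLU6(c_in, hidden, 1, 1, rng)
                            if expand != 1 else None)
        self.dw = DepthwiseConv2d(hidden, 3, stride=stride, rng=rng)
        self.dw_bn = BatchNorm2d(hidden)
        self.keep_projection = keep_projection
        if keep_projection:
            self.project = Conv2d(hidden, c_out, 1, bias=False, rng=rng)
            self.project_bn = BatchNorm2d(c_out)
        self.use_residual = (keep_projection and stride == 1
                             and c_in == c_out)
        self.out_channels = c_out if keep_projection else hidden

    def __call__(self, x, training):
        h = self.expand_conv(x, training) if self.expand_conv else x
        h = relu6(self.dw_bn(self.dw(h), training))
        if not self.keep_projection:
            return h
        h = self.project_bn(self.project(h), training)
        return t_add(h, x) if self.use_residual else h


class MobileNetV2Encoder(Module):
    """Truncated MobileNetV2: 16 bottlenecks, output stride 16.

    forward() returns the stride-16 feature mask and the skip outputs at
    strides 2, 4 and 8 needed by the U-Net decoder.
    """

    output_stride = 16

    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        a = config.alpha
        stem_c = make_divisible(32 * a)
        self.stem = _ConvBNReLU6(3, stem_c, 3, 2, rng)
        self.blocks = []
        self.skip_after = {}        # block index -> stride of its output
        c_in = stem_c
        idx = 0
        stride_now = 2
        for t, c, n, s in _MOBILENET_SETTINGS:
            c_out = make_divisible(c * a)
            for i in range(n):
                idx += 1
                stride = s if i == 0 else 1
                keep_proj = idx < _N_BOTTLENECKS
                blk = _InvertedResidual(c_in, c_out, stride, t, rng,
                                        keep_projection=keep_proj)
                stride_now *= stride
                self.blocks.append(blk)
                c_in = blk.out_channels
                if idx == _N_BOTTLENECKS:
                    break
            if idx == _N_BOTTLENECKS:
                break
        # skip points: last block at strides 4 and 8 (stride 2 is the stem)
        strides = []
        sn = 2
        idx = 0
        for t, c, n, s in _MOBILENET_SETTINGS:
            for i in range(n):
                idx += 1
                sn *= (s if i == 0 else 1)
                strides.append(sn)
                if idx == _N_BOTTLENECKS:
                    break
            if idx == _N_BOTTLENECKS:
                break
        self.skip_channels = {2: stem_c}
        for stride in (4, 8):
            last = max(i for i, sv in enumerate(strides) if sv == stride)
            self.skip_after[last] = stride
            self.skip_channels[stride] = self.blocks[last].out_channels
        self.out_channels = c_in
        if config.init == "pretrained":
            from .checkpoints import load_checkpoint
            arrays, _ = load_checkpoint(config.weights_path)
            self.set_state(arrays)

    def forward(self, x: Tensor, training: bool = False):
        h = self.stem(x, training)
        skips = {2: h}
        for i, blk in enumerate(self.blocks):
            h = blk(h, training)
            if i in self.skip_after:
                skips[self.skip_after[i]] = h
        return h, skips

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return self.forward(x, training)[0]

    def features(self, patch: np.ndarray) -> np.ndarray:
        """Normalized patch (H, W, 3) -> feature mask (C, H/16, W/16)."""
        x = as_input(normalize_patch(patch))
        return self.forward(x, training=False)[0].data[0]


@dataclass(frozen=True)
class SmallEncoderConfig:
    """Compact conv encoder for desk-scale training and tests."""
    channels: tuple = (8, 16, 16)
    strides: tuple = (2, 2, 1)
    seed: int = 0

    def __post_init__(self):
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")


class SmallEncoder(Module):
    def __init__(self, config: SmallEncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.blocks = []
        c_in = 3
        stride = 1
        self._strides = []
        for c, s in zip(config.channels, config.strides):
            self.blocks.append(_ConvBNReLU6(c_in, c, 3, s, rng))
            c_in = c
            stride *= s
            self._strides.append(stride)
        self.out_channels = c_in
        self.output_stride = stride
        self.skip_channels = dict(zip(self._strides, config.channels))

    def forward(self, x: Tensor, training: bool = False):
        h = x
        skips = {}
        for blk, stride in zip(self.blocks, self._strides):
            h = blk(h, training)
            skips[stride] = h
        return h, skips

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return self.forward(x, training)[0]

    def features(self, patch: np.ndarray) -> np.ndarray:
        x = as_input(normalize_patch(patch))
        return self.forward(x, training=False)[0].data[0]


def build_encoder(config: EncoderConfig) -> MobileNetV2Encoder:
    return MobileNetV2Encoder(config)


def build_small_encoder(config: SmallEncoderConfig) -> SmallEncoder:
    return SmallEncoder(config)


def normalize_patch(image: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Standardize a patch to zero mean and unit SD per channel.

    The SD divisor is floored at ``eps`` so constant channels map to zero
    instead of dividing by zero.
    """
    x = np.asarray(image, dtype=np.float64)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError("expected an HxWx3 image")
    mean = x.mean(axis=(0, 1), keepdims=True)
    sd = x.std(axis=(0, 1), keepdims=True)
    return (x - mean) / np.maximum(sd, eps)


def as_input(patch: np.ndarray) -> Tensor:
    """(H, W, 3) float array -> network input tensor (1, 3, H, W)."""
    return Tensor(np.transpose(np.asarray(patch, dtype=np.float64),
                               (2, 0, 1))[None], requires_grad=False)


def batch_input(patches: list[np.ndarray]) -> Tensor:
    return Tensor(np.stack([np.transpose(p, (2, 0, 1)) for p in patches]),
                  requires_grad=False)
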