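"""U-Net baseline: shared truncated encoder + 4-block expansive decoder.

Each decoder block upsamples 2x, concatenates the encoder output of the
same spatial size (the stride-8/4/2 skips; the final block, at native
resolution, has no encoder counterpart and therefore no skip), then applies
two 3x3 conv + batch-norm + ReLU stages. A final convolution without batch
norm or activation maps to one score map per class. Training uses
pixel-wise cross-entropy with batches composed of a fixed number of images
per (majority) class; artifact pixels are excluded from the loss.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .encoder import (EncoderConfig, batch_input, build_encoder,
                      normalize_patch)
from .labels import ARTIFACT, CLASS_NAMES, PREDICTED_CLASSES
from .nn import BatchNorm2d, Conv2d, Module, Tensor


@dataclass(frozen=True)
class UNetConfig:
    alpha: float = 0.75
    decoder_filters: tuple = (256, 128, 64, 32)
    steps: int = 5000
    images_per_class: int = 5
    learning_rate: float = 2e-4
    validate_every: int = 1000
    seed: int = 0
    classes: tuple = PREDICTED_CLASSES

    def __post_init__(self):
        if len(self.decoder_filters) != 4:
            raise ValueError("decoder has exactly 4 blocks")
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if min(self.images_per_class, self.validate_every) <= 0 \
                or self.learning_rate <= 0:
            raise ValueError("config values must be positive")

    @property
    def batch_size(self) -> int:
        return self.images_per_class * len(self.classes)


class _DecoderBlock(Module):
    def __init__(self, c_in, c_skip, c_out, rng):
        self.conv1 = Conv2d(c_in + c_skip, c_out, 3, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(c_out)

    def __call__(self, x, skip, training):
        h = nn.upsample2x(x)
        if skip is not None:
            if h.data.shape[2:] != skip.data.shape[2:]:
                raise ValueError(
                    f"skip shape mismatch: decoder {h.data.shape[2:]} vs "
                    f"skip {skip.data.shape[2:]}")
            h = nn.concat(h, skip)
        h = nn.relu(self.bn1(self.conv1(h), training))
        return nn.relu(self.bn2(self.conv2(h), training))


class UNet(Module):
    def __init__(self, config: UNetConfig, encoder=None):
        self.config = config
        if encoder is None:
            encoder = build_encoder(EncoderConfig(alpha=config.alpha,
                                                  seed=config.seed))
        if encoder.output_stride != 16:
            raise ValueError("U-Net decoder expects an output-stride-16 "
                             "encoder")
        for s in (8, 4, 2):
            if s not in encoder.skip_channels:
                raise ValueError(f"encoder lacks a stride-{s} skip output")
        self.encoder = encoder
        rng = np.random.default_rng(config.seed + 1)
        f = config.decoder_filters
        skips = encoder.skip_channels
        self.block1 = _DecoderBlock(encoder.out_channels, skips[8], f[0],
                                    rng)
        self.block2 = _DecoderBlock(f[0], skips[4], f[1], rng)
        self.block3 = _DecoderBlock(f[1], skips[2], f[2], rng)
        self.block4 = _DecoderBlock(f[2], 0, f[3], rng)
        self.head = Conv2d(f[3], len(config.classes), 1, bias=True,
                           rng=rng)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        bottleneck, skips = self.encoder.forward(x, training)
        h = self.block1(bottleneck, skips[8], training)
        h = self.block2(h, skips[4], training)
        h = self.block3(h, skips[2], training)
        h = self.block4(h, None, training)
        return self.head(h)

    def predict(self, patch: np.ndarray) -> np.ndarray:
        """RGB patch -> native-resolution label mask (argmax of scores)."""
        x = batch_input([normalize_patch(patch)])
        logits = self.forward(x, training=False).data[0]
        return np.asarray(self.config.classes)[np.argmax(logits, axis=0)]


def build_unet(config: UNetConfig, encoder=None) -> UNet:
    return UNet(config, encoder)


def cross_entropy_loss(logits: Tensor, masks: np.ndarray,
                       classes: tuple) -> Tensor:
    """Pixel-wise cross-entropy; ground-truth artifact pixels excluded."""
    n, k, h, w = logits.data.shape
    targets = np.zeros((n, k, h, w))
    for i, c in enumerate(classes):
        targets[:, i] = masks == c
    mask = targets.sum(axis=1)          # 1 where gt is one of the classes
    logp = nn.log_softmax(logits)
    return nn.weighted_nll(logp, targets, mask)


def majority_class(mask: np.ndarray, classes: tuple) -> int:
    """Class owning the most non-artifact pixels; ties -> lowest index."""
    counts = np.bincount(np.asarray(mask).ravel(), minlength=6)
    sub = [counts[c] for c in classes]
    return classes[int(np.argmax(sub))]


def pixel_accuracy(model: UNet, images) -> float:
    correct = total = 0
    for img in images:
        pred = model.predict(img.image)
        keep = img.mask != ARTIFACT
        correct += int((pred[keep] == img.mask[keep]).sum())
        total += int(keep.sum())
    return correct / total if total else 0.0


def train_unet(train_images, config: UNetConfig, encoder=None,
               val_images=None):
    """Train the U-Net; returns (model, history DataFrame).

    Each step's batch holds ``images_per_class`` patches per class, a patch
    belonging to the class of its majority non-artifact pixel area. Best
    validation weights are retained; deterministic given the seed.
    """
    model = UNet(config, encoder)
    pools = {c: [] for c in config.classes}
    for i, img in enumerate(train_images):
        pools[majority_class(img.mask, config.classes)].append(i)
    empty = [CLASS_NAMES[c] for c in config.classes if not pools[c]]
    if empty:
        raise ValueError("no eligible patches for classes: "
                         + ", ".join(empty))
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    norm_cache = [normalize_patch(img.image) for img in train_images]
    history = []
    best = (-np.inf, model.get_state())
    for step in range(config.steps):
        batch_idx = []
        for c in config.classes:
            pool = pools[c]
            batch_idx.extend(rng.choice(
                pool, size=config.images_per_class,
                replace=len(pool) < config.images_per_class).tolist())
        x = batch_input([norm_cache[i] for i in batch_idx])
        masks = np.stack([train_images[i].mask for i in batch_idx])
        logits = model.forward(x, training=True)
        loss = cross_entropy_loss(logits, masks, config.classes)
        opt.zero_grad()
        nn.backward(loss)
        opt.step()
        row = {"step": step + 1, "loss": float(loss.data),
               "val_score": np.nan}
        if val_images and (step + 1) % config.validate_every == 0:
            row["val_score"] = pixel_accuracy(model, val_images)
            if row["val_score"] > best[0]:
                best = (row["val_score"], model.get_state())
        history.append(row)
    if config.steps and val_images:
        if (history[-1]["step"] % config.validate_every) != 0:
            score = pixel_accuracy(model, val_images)
            history[-1]["val_score"] = score
            if score > best[0]:
                best = (score, model.get_state())
        if best[0] > -np.inf:
            model.set_state(best[1])
    return model, pd.DataFrame(history,
                               columns=["step", "loss", "val_score"])
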