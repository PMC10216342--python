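"""Reproducible desk-scale experiment protocols.

The full-scale protocol (512x512 patches, the complete backbone, 10,000
episodes / 5,000 steps) is impractical to rerun routinely, so the package
ships a scaled-down protocol used by its own test suite and by
scripts/acceptance.py: 128x128 scenes over three classes (tumor, stroma,
background) in equal proportion, a compact encoder, 200 BPN episodes and
300 U-Net steps. These sizes are the package's fixed study conditions, not
tuning knobs; docs/methods.md discusses what they do and do not show.
"""
from __future__ import annotations

from dataclasses import dataclass

from .bpn import (BPNTrainConfig, SupportSet, compute_prototypes,
                  evaluate_pixel_accuracy, train_bpn)
from .encoder import SmallEncoderConfig, build_small_encoder
from .labels import BACKGROUND, STROMA, TUMOR
from .synthetic import SyntheticDataset, TissueSceneConfig, generate_dataset
from .unet import UNetConfig, pixel_accuracy, train_unet

SCALED_CLASSES = (TUMOR, STROMA, BACKGROUND)
SCALED_PATCH = 128
SCALED_N_IMAGES = 16
BPN_EPISODES = 200
UNET_STEPS = 300


def scaled_scene_template(seed: int = 0) -> TissueSceneConfig:
    return TissueSceneConfig(
        width=SCALED_PATCH, height=SCALED_PATCH,
        class_fractions={c: 1 / 3 for c in SCALED_CLASSES},
        region_scale=48, seed=seed)


def scaled_dataset(seed: int = 0,
                   n_images: int = SCALED_N_IMAGES) -> SyntheticDataset:
    return generate_dataset(n_images, scaled_scene_template(seed),
                            seed=seed)


@dataclass
class TrainedRun:
    model: object            # encoder (BPN) or UNet
    history: object
    accuracy_untrained: float
    accuracy_trained: float
    prototypes: object = None


def run_scaled_bpn(dataset: SyntheticDataset, seed: int = 0,
                   episodes: int = BPN_EPISODES) -> TrainedRun:
    """Train the prototype network at desk scale; report held-out accuracy
    before and after training (same support set both times)."""
    train = dataset.split_images("train")
    val = dataset.split_images("val")
    test = dataset.split_images("test")
    enc = build_small_encoder(SmallEncoderConfig(seed=seed))
    sup = SupportSet([(im.image, im.mask) for im in train[:5]])
    protos0 = compute_prototypes(sup, enc, SCALED_CLASSES)
    acc0 = evaluate_pixel_accuracy(enc, protos0, test, SCALED_CLASSES)
    cfg = BPNTrainConfig(episodes=episodes, supports_per_class=2,
                         queries_per_episode=1, validate_every=50,
                         seed=seed, classes=SCALED_CLASSES)
    enc, history = train_bpn(train, cfg, encoder=enc, val_images=val)
    protos1 = compute_prototypes(sup, enc, SCALED_CLASSES)
    acc1 = evaluate_pixel_accuracy(enc, protos1, test, SCALED_CLASSES)
    return TrainedRun(enc, history, acc0, acc1, prototypes=protos1)


def run_scaled_unet(dataset: SyntheticDataset, seed: int = 0,
                    steps: int = UNET_STEPS) -> TrainedRun:
    """Train the U-Net baseline at desk scale; report held-out accuracy
    before and after training."""
    train = dataset.split_images("train")
    val = dataset.split_images("val")
    test = dataset.split_images("test")

    def build():
        enc = build_small_encoder(SmallEncoderConfig(
            channels=(8, 12, 16, 24), strides=(2, 2, 2, 2), seed=seed))
        return enc

    cfg0 = UNetConfig(steps=0, images_per_class=2,
                      decoder_filters=(16, 12, 8, 8), validate_every=50,
                      seed=seed, classes=SCALED_CLASSES)
    model0, _ = train_unet(train, cfg0, encoder=build(), val_images=val)
    acc0 = pixel_accuracy(model0, test)
    cfg = UNetConfig(steps=steps, images_per_class=2,
                     decoder_filters=(16, 12, 8, 8), validate_every=50,
                     seed=seed, classes=SCALED_CLASSES)
    model, history = train_unet(train, cfg, encoder=build(),
                                val_images=val)
    acc1 = pixel_accuracy(model, test)
    return TrainedRun(model, history, acc0, acc1)
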