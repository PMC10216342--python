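"""Runnable segmenters and their single-file checkpoints."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bpn import PrototypeSet, segment_query
from .checkpoints import load_checkpoint, save_checkpoint
from .encoder import (EncoderConfig, SmallEncoderConfig, build_encoder,
                      build_small_encoder)
from .unet import UNet, UNetConfig


def encoder_meta(encoder) -> dict:
    cfg = encoder.config
    if isinstance(cfg, SmallEncoderConfig):
        return {"type": "small", "channels": list(cfg.channels),
                "strides": list(cfg.strides), "seed": cfg.seed}
    return {"type": "mobilenet", "alpha": cfg.alpha,
            "patch_size": cfg.patch_size, "seed": cfg.seed}


def encoder_from_meta(meta: dict):
    if meta["type"] == "small":
        return build_small_encoder(SmallEncoderConfig(
            channels=tuple(meta["channels"]),
            strides=tuple(meta["strides"]), seed=meta["seed"]))
    return build_encoder(EncoderConfig(alpha=meta["alpha"],
                                       patch_size=meta["patch_size"],
                                       seed=meta["seed"]))


@dataclass
class BPNSegmenter:
    encoder: object
    prototypes: PrototypeSet

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        return segment_query(patch, self.prototypes, self.encoder).labels

    def save(self, path) -> None:
        classes = self.prototypes.classes
        arrays = self.encoder.get_state()
        n_state = len(arrays)
        arrays.append(self.prototypes.matrix(classes))
        save_checkpoint(path, arrays, {
            "kind": "bpn", "encoder": encoder_meta(self.encoder),
            "classes": list(classes), "n_state": n_state,
            "n_support": {str(c): int(v) for c, v in
                          self.prototypes.n_support_per_class.items()}})


@dataclass
class UNetSegmenter:
    model: UNet

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        return self.model.predict(patch)

    def save(self, path) -> None:
        cfg = self.model.config
        save_checkpoint(path, self.model.get_state(), {
            "kind": "unet", "encoder": encoder_meta(self.model.encoder),
            "classes": list(cfg.classes),
            "decoder_filters": list(cfg.decoder_filters),
            "alpha": cfg.alpha, "seed": cfg.seed})


def load_segmenter(path):
    arrays, meta = load_checkpoint(path)
    encoder = encoder_from_meta(meta["encoder"])
    if meta["kind"] == "bpn":
        n_state = meta["n_state"]
        encoder.set_state(arrays[:n_state])
        pm = arrays[n_state]
        classes = tuple(meta["classes"])
        protos = PrototypeSet(
            prototypes={c: pm[i] for i, c in enumerate(classes)},
            n_support_per_class={int(c): v for c, v in
                                 meta.get("n_support", {}).items()})
        return BPNSegmenter(encoder, protos)
    if meta["kind"] == "unet":
        cfg = UNetConfig(alpha=meta["alpha"],
                         decoder_filters=tuple(meta["decoder_filters"]),
                         classes=tuple(meta["classes"]), seed=meta["seed"])
        model = UNet(cfg, encoder)
        model.set_state(arrays)
        return UNetSegmenter(model)
    raise ValueError(f"unknown checkpoint kind {meta.get('kind')!r}")
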