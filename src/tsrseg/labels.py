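"""Tissue class schema: indices, names, display palette, mask encoding.

Six classes are used for annotation; the artifact class (index 5) marks
regions that are ignored during training and evaluation and never appears
in predictions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

TUMOR, STROMA, NECROSIS, MUCUS, BACKGROUND, ARTIFACT = range(6)

CLASS_NAMES = ("tumor", "stroma", "necrosis", "mucus", "background",
               "artifact")

#: Display palette: blue tumor, orange stroma, yellow necrosis,
#: magenta mucus, white background; artifact drawn dark gray.
PALETTE = (
    (0, 0, 255),
    (255, 165, 0),
    (255, 255, 0),
    (255, 0, 255),
    (255, 255, 255),
    (64, 64, 64),
)

#: Classes that may appear in predictions.
PREDICTED_CLASSES = (TUMOR, STROMA, NECROSIS, MUCUS, BACKGROUND)
N_PREDICTED = len(PREDICTED_CLASSES)
IGNORE_INDEX = ARTIFACT


@dataclass(frozen=True)
class LabelSchema:
    """Ordered class table shared by all modules."""
    classes: tuple = field(default_factory=lambda: tuple(
        (i, CLASS_NAMES[i], PALETTE[i]) for i in range(6)))
    ignore_index: int = IGNORE_INDEX

    def __post_init__(self):
        if len(self.classes) != 6:
            raise ValueError("schema requires exactly 6 classes")
        colors = [c for _, _, c in self.classes]
        if len(set(colors)) != 6:
            raise ValueError("palette colors must be unique")
        if self.ignore_index != 5:
            raise ValueError("ignore_index must be the artifact class (5)")

    @property
    def names(self):
        return tuple(n for _, n, _ in self.classes)

    @property
    def palette(self):
        return tuple(c for _, _, c in self.classes)


DEFAULT_SCHEMA = LabelSchema()


def encode_mask(color_image: np.ndarray,
                schema: LabelSchema = DEFAULT_SCHEMA) -> np.ndarray:
    """Map an RGB palette image to an integer label mask.

    Raises ValueError naming the offending pixel color if any pixel is not
    one of the 6 palette colors.
    """
    img = np.asarray(color_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB array")
    out = np.full(img.shape[:2], -1, dtype=np.int64)
    for idx, _, color in schema.classes:
        out[np.all(img == np.asarray(color, dtype=img.dtype), axis=2)] = idx
    if (out < 0).any():
        r, c = np.argwhere(out < 0)[0]
        raise ValueError(
            f"unknown color {tuple(int(v) for v in img[r, c])} at "
            f"pixel ({r}, {c}); not in the class palette")
    return out


def decode_mask(mask: np.ndarray,
                schema: LabelSchema = DEFAULT_SCHEMA) -> np.ndarray:
    """Map an integer label mask to its RGB palette image."""
    m = np.asarray(mask)
    if m.size and (m.min() < 0 or m.max() > 5):
        raise ValueError(f"label values out of range 0..5: "
                         f"min={m.min()}, max={m.max()}")
    lut = np.asarray(schema.palette, dtype=np.uint8)
    return lut[m]


def save_mask_png(mask: np.ndarray, path,
                  schema: LabelSchema = DEFAULT_SCHEMA) -> None:
    """Write a label mask as an 8-bit indexed PNG with embedded palette."""
    m = np.asarray(mask)
    if m.size and (m.min() < 0 or m.max() > 5):
        raise ValueError("label values out of range 0..5")
    img = Image.fromarray(m.astype(np.uint8), mode="P")
    pal = [v for color in schema.palette for v in color]
    img.putpalette(pal + [0] * (768 - len(pal)))
    img.save(path)


def load_mask_png(path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "P":
        raise ValueError(f"{path}: expected an indexed (palette) PNG")
    return np.asarray(img, dtype=np.int64)


def save_image_png(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def load_image_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
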