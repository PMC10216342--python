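"""Tiling of large ROIs into fixed-size patches and result stitching.

Two stitch rules are supported:

* method A — patches tile with stride = patch size; the last row/column is
  shifted so patches end exactly at the image edge, and in the resulting
  overlap the later (row-major) patch's labels win. No averaging.
* method B — a fixed boundary strip of each patch is discarded (the model
  has the least context there), so patches overlap with stride
  patch_size - 2*boundary and each pixel is written exactly once. Patches
  touching the image border keep their border-side margin.

Coordinates are 0-based; rectangles are half-open [r0, r1) x [c0, c1).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TilingConfig:
    patch_size: int = 512
    boundary: int = 96
    method: str = "B"

    def __post_init__(self):
        if self.method not in ("A", "B"):
            raise ValueError("method must be 'A' or 'B'")
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if self.method == "B" and not 0 < 2 * self.boundary < self.patch_size:
            raise ValueError("boundary must satisfy 0 < 2*boundary "
                             "< patch_size")

    @property
    def active_edge(self) -> int:
        """Edge length of the interior active area (method B)."""
        return self.patch_size - 2 * self.boundary

    @property
    def active_area_fraction(self) -> float:
        """Fraction of a patch whose output is kept (method B interior)."""
        return (self.active_edge / self.patch_size) ** 2


@dataclass(frozen=True)
class TilingPlan:
    image_size: tuple
    config: TilingConfig
    origins: tuple                 # ((r0, c0), ...) patch top-left corners
    active_regions: tuple          # ((r0, r1, c0, c1), ...) written rects

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid, ((r, c), (ar0, ar1, ac0, ac1)) in enumerate(
                zip(self.origins, self.active_regions)):
            rows.append({"patch_id": pid, "r0": r, "c0": c,
                         "active_r0": ar0, "active_r1": ar1,
                         "active_c0": ac0, "active_c1": ac1})
        return pd.DataFrame(rows)


def _axis_origins(length: int, patch: int, stride: int) -> list[int]:
    """Patch start offsets along one axis; last patch ends at the edge."""
    origins = [0]
    while origins[-1] + patch < length:
        nxt = origins[-1] + stride
        if nxt + patch >= length:
            nxt = length - patch
        origins.append(nxt)
    return origins


def plan_tiling(image_size: tuple, config: TilingConfig) -> TilingPlan:
    h, w = image_size
    ps = config.patch_size
    if h < ps or w < ps:
        raise ValueError(f"image {h}x{w} smaller than patch size {ps}")
    if config.method == "A":
        rows = _axis_origins(h, ps, ps)
        cols = _axis_origins(w, ps, ps)
        origins, active = [], []
        for r in rows:
            for c in cols:
                origins.append((r, c))
                active.append((r, r + ps, c, c + ps))
        return TilingPlan((h, w), config, tuple(origins), tuple(active))

    b = config.boundary
    stride = ps - 2 * b
    rows = _axis_origins(h, ps, stride)
    cols = _axis_origins(w, ps, stride)

    def axis_active(origins, length):
        spans = []
        prev_end = 0
        for i, o in enumerate(origins):
            start = 0 if i == 0 else max(prev_end, o + b)
            end = length if i == len(origins) - 1 else o + ps - b
            # a shifted final patch writes only the yet-uncovered remainder
            start = max(start, prev_end)
            spans.append((start, end))
            prev_end = end
        return spans

    rspans = axis_active(rows, h)
    cspans = axis_active(cols, w)
    origins, active = [], []
    for r, (ar0, ar1) in zip(rows, rspans):
        for c, (ac0, ac1) in zip(cols, cspans):
            origins.append((r, c))
            active.append((ar0, ar1, ac0, ac1))
    return TilingPlan((h, w), config, tuple(origins), tuple(active))


def segment_large(image: np.ndarray, segmenter,
                  config: TilingConfig) -> np.ndarray:
    """Run a patch segmenter over a large image and stitch a full mask.

    ``segmenter`` maps an RGB patch (ps, ps, 3) to a label mask (ps, ps).
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    plan = plan_tiling((h, w), config)
    ps = config.patch_size
    out = np.full((h, w), -1, dtype=np.int64)
    for (r, c), (ar0, ar1, ac0, ac1) in zip(plan.origins,
                                            plan.active_regions):
        pred = np.asarray(segmenter(img[r:r + ps, c:c + ps]))
        if pred.shape != (ps, ps):
            raise ValueError(f"segmenter returned shape {pred.shape}, "
                             f"expected ({ps}, {ps})")
        out[ar0:ar1, ac0:ac1] = pred[ar0 - r:ar1 - r, ac0 - c:ac1 - c]
    assert (out >= 0).all(), "tiling plan left pixels unwritten"
    return out


def coverage_map(plan: TilingPlan) -> np.ndarray:
    """Number of times each pixel is written by the plan's active regions."""
    h, w = plan.image_size
    cov = np.zeros((h, w), dtype=np.int64)
    for ar0, ar1, ac0, ac1 in plan.active_regions:
        cov[ar0:ar1, ac0:ac1] += 1
    return cov
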