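"""Tumor-stroma ratio (TSR) from label masks.

TSR is the tumor area divided by the combined tumor + stroma area, in
percent. Necrosis, mucus and background pixels are excluded from both
numerator and denominator, so the score is well defined even in regions
containing necrotic or mucinous tissue.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .labels import STROMA, TUMOR


@dataclass(frozen=True)
class TSRResult:
    tumor_px: int
    stroma_px: int

    @property
    def tsr_percent(self) -> float:
        return 100.0 * self.tumor_px / (self.tumor_px + self.stroma_px)


@dataclass(frozen=True)
class TSRCategory:
    label: str              # "stroma-low" | "stroma-high"
    cutoff_percent: float


def compute_tsr(mask: np.ndarray) -> TSRResult:
    """Count tumor and stroma pixels of a 5-class mask and form the TSR."""
    m = np.asarray(mask)
    if m.size and (m.min() < 0 or m.max() > 4):
        raise ValueError("compute_tsr expects a predicted mask with "
                         "values in 0..4")
    tumor = int((m == TUMOR).sum())
    stroma = int((m == STROMA).sum())
    if tumor + stroma == 0:
        raise ValueError("TSR undefined: no tumor or stroma pixels in mask")
    return TSRResult(tumor_px=tumor, stroma_px=stroma)


def categorize_tsr(tsr_percent: float, cutoff: float = 50.0) -> TSRCategory:
    """Categorize a TSR percent as stroma-low (high tumor fraction) or
    stroma-high.

    A TSR above the cutoff means little stroma, hence "stroma-low"; ties at
    the cutoff are assigned to stroma-low for determinism.
    """
    if not 0.0 <= tsr_percent <= 100.0:
        raise ValueError("tsr_percent must be in [0, 100]")
    if cutoff not in (50.0, 65.0, 50, 65):
        warnings.warn(f"non-standard TSR cutoff {cutoff} "
                      "(usual values are 50 or 65)", stacklevel=2)
    label = "stroma-low" if tsr_percent >= cutoff else "stroma-high"
    return TSRCategory(label=label, cutoff_percent=float(cutoff))


def tsr_deviation(a_percent: float, b_percent: float) -> float:
    """Signed difference a - b in percentage points."""
    return float(a_percent) - float(b_percent)
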