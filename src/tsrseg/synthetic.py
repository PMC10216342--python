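"""Synthetic H&E-like scenes with exact ground truth, and simulated raters.

Scenes are built from a seeded Voronoi tessellation whose boundaries are
warped by a smooth random displacement field (organic-looking regions,
still with exact per-pixel labels). Cells are assigned to tissue classes
greedily by largest remaining area deficit, so measured class fractions
track the requested ones. Each class gets a distinct texture loosely
mimicking H&E appearance: tumor as dense dark-purple nuclei on a lavender
bed, stroma as oriented pink fibers, necrosis as pale granular debris,
mucus as a smooth light blue-gray, background as near-white glass.

The rater simulator adds a systematic bias (in percentage points) and
Gaussian noise to true TSR values, clipped to [0, 100] — the simplest
model of the human over/under-estimation the agreement analysis studies.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .agreement import RaterTable
from .labels import (ARTIFACT, BACKGROUND, CLASS_NAMES, MUCUS, NECROSIS,
                     STROMA, TUMOR)

TISSUE_CLASSES = (TUMOR, STROMA, NECROSIS, MUCUS, BACKGROUND)


@dataclass(frozen=True)
class TextureParams:
    nucleus_density: float = 0.35       # tumor area fraction covered by nuclei
    fiber_contrast: float = 0.55        # stroma stripe modulation depth
    fiber_wavelength: float = 14.0      # px between stroma fibers
    orientation_spread: float = 0.35    # rad, fiber direction wobble
    color_jitter: float = 6.0           # per-scene base color jitter (8-bit)
    pixel_noise: float = 3.0            # per-pixel Gaussian noise SD (8-bit)


@dataclass(frozen=True)
class TissueSceneConfig:
    width: int = 512
    height: int = 512
    class_fractions: dict = field(default_factory=lambda: {
        TUMOR: 0.35, STROMA: 0.35, NECROSIS: 0.10, MUCUS: 0.05,
        BACKGROUND: 0.15})
    region_scale: int = 96
    artifact_fraction: float = 0.0
    texture_params: TextureParams = field(default_factory=TextureParams)
    seed: int = 0

    def __post_init__(self):
        if self.width < 64 or self.height < 64:
            raise ValueError("scene must be at least 64x64 pixels")
        bad = set(self.class_fractions) - set(TISSUE_CLASSES)
        if bad:
            raise ValueError(f"unknown classes in fractions: {bad}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if not 0.0 <= self.artifact_fraction < 1.0:
            raise ValueError("artifact_fraction must be in [0, 1)")


@dataclass
class LabeledImage:
    image: np.ndarray          # (H, W, 3) uint8
    mask: np.ndarray           # (H, W) int64, values 0..5
    name: str = ""


@dataclass(frozen=True)
class RaterSimConfig:
    n_rois: int = 30
    n_raters: int = 10
    bias_pp: float = 0.0
    noise_sd_pp: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd_pp < 0:
            raise ValueError("noise_sd_pp must be >= 0")
        if self.n_rois < 1 or self.n_raters < 1:
            raise ValueError("need at least one ROI and one rater")


# ------------------------------------------------------------- geometry

def _voronoi_labels(cfg: TissueSceneConfig,
                    rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.height, cfg.width
    n_cells = max(len(cfg.class_fractions),
                  int(round(h * w / cfg.region_scale ** 2)))
    seeds = np.column_stack([rng.uniform(0, h, n_cells),
                             rng.uniform(0, w, n_cells)])
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    # smooth warp of lookup coordinates -> organic region boundaries
    sigma = max(4.0, cfg.region_scale / 3.0)
    amp = cfg.region_scale / 4.0
    for axis_grid in (rr, cc):
        noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
        sd = noise.std()
        if sd > 0:
            axis_grid += amp * noise / sd
    _, cell = cKDTree(seeds).query(
        np.column_stack([rr.ravel(), cc.ravel()]), workers=1)
    cell = cell.reshape(h, w)

    areas = np.bincount(cell.ravel(), minlength=n_cells)
    targets = {c: f * (1 - cfg.artifact_fraction) * h * w
               for c, f in cfg.class_fractions.items()}
    if cfg.artifact_fraction > 0:
        targets[ARTIFACT] = cfg.artifact_fraction * h * w
    classes = list(targets)
    deficit = {c: targets[c] for c in classes}
    cell_class = np.zeros(n_cells, dtype=np.int64)
    order = sorted(rng.permutation(n_cells), key=lambda i: -areas[i])
    for i in order:
        best = max(classes, key=lambda c: deficit[c])
        cell_class[i] = best
        deficit[best] -= areas[i]
    return cell_class[cell]


# ------------------------------------------------------------- textures

def _smooth_noise(rng, shape, sigma):
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = n.std()
    return n / sd if sd > 0 else n


def _jitter(rng, color, amount):
    return np.asarray(color, float) + rng.uniform(-amount, amount, 3)


def _render(mask: np.ndarray, tp: TextureParams,
            rng: np.random.Generator) -> np.ndarray:
    h, w = mask.shape
    img = np.zeros((h, w, 3))
    j = tp.color_jitter

    if (mask == TUMOR).any():
        base = _jitter(rng, (172, 122, 186), j)
        nuc = _jitter(rng, (86, 52, 130), j)
        g = _smooth_noise(rng, (h, w), 2.2)
        thr = np.quantile(g, 1.0 - tp.nucleus_density)
        tex = np.where((g >= thr)[..., None], nuc, base)
        img[mask == TUMOR] = tex[mask == TUMOR]

    if (mask == STROMA).any():
        base = _jitter(rng, (233, 170, 193), j)
        fiber = _jitter(rng, (207, 124, 162), j)
        theta = rng.uniform(0, np.pi) \
            + tp.orientation_spread * _smooth_noise(rng, (h, w), 24.0)
        rr, cc = np.mgrid[0:h, 0:w]
        phase = 4.0 * _smooth_noise(rng, (h, w), 8.0)
        stripe = np.sin(2 * np.pi * (rr * np.cos(theta) + cc * np.sin(theta))
                        / tp.fiber_wavelength + phase)
        mix = 0.5 * tp.fiber_contrast * (1 + stripe)
        tex = base[None, None] * (1 - mix[..., None]) \
            + fiber[None, None] * mix[..., None]
        img[mask == STROMA] = tex[mask == STROMA]

    if (mask == NECROSIS).any():
        base = _jitter(rng, (226, 199, 183), j)
        speck = rng.uniform(-24, 24, (h, w, 1))
        tex = base[None, None] + speck
        img[mask == NECROSIS] = tex[mask == NECROSIS]

    if (mask == MUCUS).any():
        base = _jitter(rng, (214, 226, 236), j)
        tex = base[None, None] \
            + 8.0 * _smooth_noise(rng, (h, w), 12.0)[..., None]
        img[mask == MUCUS] = tex[mask == MUCUS]

    if (mask == BACKGROUND).any():
        base = _jitter(rng, (247, 247, 247), j / 2)
        img[mask == BACKGROUND] = base

    if (mask == ARTIFACT).any():
        img[mask == ARTIFACT] = (60, 60, 60)

    img += rng.normal(0, tp.pixel_noise, (h, w, 3))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_scene(config: TissueSceneConfig) -> LabeledImage:
    """Generate one labeled scene; bit-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    mask = _voronoi_labels(config, rng)
    image = _render(mask, config.texture_params, rng)
    return LabeledImage(image=image, mask=mask,
                        name=f"scene_{config.seed:06d}")


# -------------------------------------------------------------- dataset

@dataclass
class SyntheticDataset:
    images: list
    splits: dict                  # split name -> list of image indices

    def split_images(self, split: str) -> list:
        return [self.images[i] for i in self.splits[split]]

    def census(self) -> pd.DataFrame:
        """Per-split class-pixel counts (rows: splits, columns: classes)."""
        rows = {}
        for split, idxs in self.splits.items():
            counts = np.zeros(6, dtype=np.int64)
            for i in idxs:
                counts += np.bincount(self.images[i].mask.ravel(),
                                      minlength=6)
            rows[split] = counts
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=list(CLASS_NAMES))


def _split_sizes(n: int, fractions=(0.6, 0.2, 0.2)) -> tuple:
    sizes = [max(1, int(round(f * n))) for f in fractions]
    while sum(sizes) > n:
        sizes[int(np.argmax(sizes))] -= 1
    sizes[0] += n - sum(sizes)
    return tuple(sizes)


def generate_dataset(n_images: int, template: TissueSceneConfig,
                     seed: int = 0, concentration: float = 8.0
                     ) -> SyntheticDataset:
    """Generate a dataset of scenes with disjoint train/val/test splits.

    Per-image class fractions are drawn from a Dirichlet centered on the
    template's fractions so that individual scenes vary in composition
    (and in particular in majority class).
    """
    if n_images < 3:
        raise ValueError("need n_images >= 3 for disjoint splits")
    rng = np.random.default_rng(seed)
    classes = [c for c, f in template.class_fractions.items() if f > 0]
    alpha = np.array([template.class_fractions[c] for c in classes])
    images = []
    for i in range(n_images):
        fr = rng.dirichlet(concentration * alpha)
        cfg = replace(template,
                      class_fractions=dict(zip(classes, fr.tolist())),
                      seed=int(rng.integers(0, 2 ** 31 - 1)))
        img = generate_scene(cfg)
        img.name = f"img_{i:04d}"
        images.append(img)
    perm = rng.permutation(n_images)
    n_tr, n_va, n_te = _split_sizes(n_images)
    splits = {"train": sorted(perm[:n_tr].tolist()),
              "val": sorted(perm[n_tr:n_tr + n_va].tolist()),
              "test": sorted(perm[n_tr + n_va:].tolist())}
    return SyntheticDataset(images=images, splits=splits)


# ---------------------------------------------------------------- raters

def simulate_raters(true_tsr, config: RaterSimConfig) -> RaterTable:
    """Simulate observers estimating TSR with bias and noise.

    estimate(r, i) = clip(100 * true_tsr[i] + bias_pp + eps, 0, 100),
    eps ~ Normal(0, noise_sd_pp^2), seeded.
    """
    true_tsr = np.asarray(list(true_tsr), dtype=float)
    if true_tsr.size and (true_tsr.min() < 0 or true_tsr.max() > 1):
        raise ValueError("true TSR values must be fractions in [0, 1]")
    if len(true_tsr) != config.n_rois:
        raise ValueError(f"config expects {config.n_rois} ROIs, got "
                         f"{len(true_tsr)}")
    rng = np.random.default_rng(config.seed)
    eps = rng.normal(0.0, config.noise_sd_pp,
                     (config.n_rois, config.n_raters))
    est = np.clip(100.0 * true_tsr[:, None] + config.bias_pp + eps,
                  0.0, 100.0)
    obs = [f"obs{r + 1:02d}" for r in range(config.n_raters)]
    df = pd.DataFrame(est, columns=obs,
                      index=pd.Index(range(1, config.n_rois + 1),
                                     name="roi_id"))
    return RaterTable(df, {o: "simulated" for o in obs})
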