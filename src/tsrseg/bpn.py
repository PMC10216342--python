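"""Basic Prototype Network: few-shot segmentation via class prototypes.

Each class is represented by a prototype — the mean latent vector obtained
by masked average pooling of support-image features over the class's
annotation, averaged across supports. A query pixel (feature cell) is
scored against every prototype with the similarity -0.5 * ||x - p||^2 and
assigned to the closest one; per-class score maps are bilinearly upsampled
to native resolution before the argmax. Training is episodic: each episode
samples supports and queries, rebuilds prototypes from the supports and
applies a pixel-wise loss (cross-entropy over prototype similarities plus
a prototype-attraction term pulling cell features toward their true-class
prototype, weighted by gamma).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .encoder import (EncoderConfig, batch_input, build_encoder,
                      normalize_patch)
from .labels import ARTIFACT, CLASS_NAMES, PREDICTED_CLASSES
from .nn import Tensor

logger = logging.getLogger(__name__)


@dataclass
class SupportSet:
    """Annotated (image, mask) example pairs."""
    items: list                     # [(patch HxWx3, mask HxW), ...]

    def __post_init__(self):
        for _, mask in self.items:
            m = np.asarray(mask)
            if m.size and (m.min() < 0 or m.max() > ARTIFACT):
                raise ValueError("support mask values must be in 0..5")

    @property
    def classes_present(self) -> set:
        present = set()
        for _, mask in self.items:
            present |= set(np.unique(mask).tolist())
        return present - {ARTIFACT}


@dataclass
class PrototypeSet:
    prototypes: dict                # class index -> latent vector
    n_support_per_class: dict

    @property
    def classes(self) -> tuple:
        return tuple(sorted(self.prototypes))

    def matrix(self, classes=None) -> np.ndarray:
        classes = self.classes if classes is None else tuple(classes)
        missing = [c for c in classes if c not in self.prototypes]
        if missing:
            raise ValueError(f"missing prototypes for classes {missing}")
        return np.stack([self.prototypes[c] for c in classes])


@dataclass(frozen=True)
class BPNTrainConfig:
    episodes: int = 10_000
    supports_per_class: int = 5
    queries_per_episode: int = 2
    learning_rate: float = 5e-4
    gamma: float = 0.5
    alpha: float = 1.0
    validate_every: int = 1000
    seed: int = 0
    classes: tuple = PREDICTED_CLASSES

    def __post_init__(self):
        if min(self.supports_per_class, self.queries_per_episode,
               self.validate_every) <= 0 or self.learning_rate <= 0:
            raise ValueError("config values must be positive")
        if self.episodes < 0:
            raise ValueError("episodes must be >= 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")


@dataclass
class SegmentationResult:
    labels: np.ndarray              # (H, W) native-resolution classes
    score_maps: np.ndarray          # (K, H, W) upsampled similarities
    cell_labels: np.ndarray         # (h, w) pre-upsampling argmax
    classes: tuple


# ------------------------------------------------------------ primitives

def downsample_annotation(mask: np.ndarray,
                          target_shape: tuple) -> np.ndarray:
    """Fractional per-class coverage weights on the feature grid.

    Returns a (6, h, w) array where entry (c, i, j) is the fraction of
    native pixels in feature cell (i, j) annotated as class c; the six
    weights sum to 1 in every cell.
    """
    m = np.asarray(mask)
    th, tw = target_shape
    if m.ndim != 2 or m.shape[0] % th or m.shape[1] % tw:
        raise ValueError(f"mask shape {m.shape} not divisible into "
                         f"({th}, {tw}) cells")
    if m.size and (m.min() < 0 or m.max() > ARTIFACT):
        raise ValueError("mask values must be in 0..5")
    fh, fw = m.shape[0] // th, m.shape[1] // tw
    onehot = (m[None] == np.arange(6)[:, None, None]).astype(np.float64)
    return onehot.reshape(6, th, fh, tw, fw).mean(axis=(2, 4))


def similarity(x: np.ndarray, p: np.ndarray) -> float:
    """Similarity of a feature vector to a prototype: -0.5 * ||x - p||^2."""
    x = np.asarray(x, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if x.shape != p.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {p.shape}")
    d = x - p
    return float(-0.5 * d @ d)


def _prototype_tensors(feats: Tensor, weights: np.ndarray,
                       classes: tuple) -> tuple[Tensor, dict]:
    """Per-class prototype tensors from a batch of support features.

    weights: (N, 6, h, w) fractional coverage per support image. For each
    class, one masked-mean vector per support that contains the class,
    then an unweighted mean over those supports.
    """
    n = feats.data.shape[0]
    vectors = []
    n_support = {}
    missing = []
    for c in classes:
        per_support = []
        for i in range(n):
            w = np.zeros(weights.shape[0:1] + weights.shape[2:])
            if weights[i, c].sum() > 0:
                w[i] = weights[i, c]
                per_support.append(nn.masked_mean(feats, w))
        if not per_support:
            missing.append(c)
            continue
        n_support[c] = len(per_support)
        vectors.append(nn.mean_vectors(per_support))
    if missing:
        raise ValueError(
            "classes absent from all supports: "
            + ", ".join(CLASS_NAMES[c] for c in missing))
    return nn.stack_vectors(vectors), n_support


def compute_prototypes(supports: SupportSet, encoder,
                       classes: tuple | None = None) -> PrototypeSet:
    """Masked-average-pool support features into one prototype per class."""
    if classes is None:
        classes = tuple(sorted(supports.classes_present))
    patches = [normalize_patch(img) for img, _ in supports.items]
    x = batch_input(patches)
    feats = encoder(x, training=False)
    _, _, fh, fw = feats.data.shape
    weights = np.stack([downsample_annotation(mask, (fh, fw))
                        for _, mask in supports.items])
    protos, n_support = _prototype_tensors(feats, weights, classes)
    return PrototypeSet(
        prototypes={c: protos.data[i] for i, c in enumerate(classes)},
        n_support_per_class=n_support)


def bilinear_resize(a: np.ndarray, out_shape: tuple) -> np.ndarray:
    """Bilinear upsampling with half-pixel-aligned sample centers."""
    h, w = a.shape
    oh, ow = out_shape

    def axis_coords(n_in, n_out):
        x = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        x = np.clip(x, 0, n_in - 1)
        x0 = np.floor(x).astype(int)
        x1 = np.minimum(x0 + 1, n_in - 1)
        return x0, x1, x - x0

    r0, r1, fr = axis_coords(h, oh)
    c0, c1, fc = axis_coords(w, ow)
    rows = a[r0] * (1 - fr[:, None]) + a[r1] * fr[:, None]
    return rows[:, c0] * (1 - fc) + rows[:, c1] * fc


def segment_query(query: np.ndarray, prototypes: PrototypeSet, encoder,
                  classes: tuple | None = None) -> SegmentationResult:
    """Label a query patch by its nearest prototype per feature cell.

    Per-class similarity maps are bilinearly upsampled to the native
    resolution before the argmax; ties go to the lowest class index.
    """
    classes = prototypes.classes if classes is None else tuple(classes)
    pm = prototypes.matrix(classes)                # raises if missing
    feats = encoder.features(query)                # (C, h, w)
    c, fh, fw = feats.shape
    diff = feats[None] - pm[:, :, None, None]
    scores = -0.5 * np.einsum("kchw,kchw->khw", diff, diff)
    h, w = query.shape[:2]
    up = np.stack([bilinear_resize(s, (h, w)) for s in scores])
    classes_arr = np.asarray(classes)
    return SegmentationResult(
        labels=classes_arr[np.argmax(up, axis=0)],
        score_maps=up,
        cell_labels=classes_arr[np.argmax(scores, axis=0)],
        classes=classes)


def corel_pixel_loss(score_maps: Tensor, target_weights: np.ndarray,
                     gamma: float, sample_mask: np.ndarray | None = None
                     ) -> Tensor:
    """Pixel-wise loss: cross-entropy + gamma * prototype attraction.

    ``score_maps`` are prototype similarities (N, K, h, w);
    ``target_weights`` are fractional class coverages (N, K, h, w) in the
    same class order (artifact excluded, not renormalized — cells that are
    partly artifact contribute with reduced weight, fully-artifact cells
    not at all). The attraction term is the mean squared feature-prototype
    distance of each cell to its majority-class prototype, recovered from
    the similarity as -2 * score. ``sample_mask`` (N,) optionally restricts
    the loss to a subset of batch items (e.g. queries only).
    """
    s = score_maps.data
    if not np.isfinite(s).all():
        raise ValueError("non-finite similarity scores")
    if target_weights.shape != s.shape:
        raise ValueError("target weight shape mismatch")
    labeled = target_weights.sum(axis=1)           # (N, h, w), in [0, 1]
    if sample_mask is not None:
        labeled = labeled * sample_mask[:, None, None]
    if labeled.sum() <= 0:
        raise ValueError("no labeled cells in loss")
    # cross-entropy of softmax similarities against fractional targets
    logp = nn.log_softmax(score_maps)
    frac = np.divide(target_weights, np.maximum(labeled[:, None], 1e-12))
    ce = nn.weighted_nll(logp, frac, labeled)
    # prototype attraction: ||f - p_true||^2 = -2 * s_true
    true_cls = np.argmax(target_weights, axis=1)   # ties -> lowest index
    onehot = np.eye(s.shape[1])[true_cls].transpose(0, 3, 1, 2)
    cell_on = (labeled > 0).astype(np.float64)
    w_r = -2.0 * onehot * cell_on[:, None] / cell_on.sum()
    r = nn.inner(score_maps, w_r)
    return nn.combine([(1.0, ce), (float(gamma), r)])


# -------------------------------------------------------------- training

def _class_pool(images, classes):
    pool = {c: [] for c in classes}
    for i, img in enumerate(images):
        present = set(np.unique(img.mask).tolist())
        for c in classes:
            if c in present:
                pool[c].append(i)
    missing = [CLASS_NAMES[c] for c in classes if not pool[c]]
    if missing:
        raise ValueError(f"dataset lacks classes: {', '.join(missing)}")
    return pool


def evaluate_pixel_accuracy(encoder, prototypes: PrototypeSet,
                            images, classes=None) -> float:
    """Mean fraction of non-artifact pixels labeled correctly."""
    correct = total = 0
    for img in images:
        res = segment_query(img.image, prototypes, encoder, classes)
        keep = img.mask != ARTIFACT
        correct += int((res.labels[keep] == img.mask[keep]).sum())
        total += int(keep.sum())
    return correct / total if total else 0.0


def _episode_batch(images, pool, rng, cfg):
    support_sel = {}
    for c in cfg.classes:
        idx = pool[c]
        replace = len(idx) < cfg.supports_per_class
        support_sel[c] = rng.choice(idx, size=cfg.supports_per_class,
                                    replace=replace)
    all_support = sorted({int(i) for sel in support_sel.values()
                          for i in sel})
    n_q = min(cfg.queries_per_episode, len(images))
    queries = rng.choice(len(images), size=n_q, replace=False)
    batch_idx = all_support + [int(q) for q in queries]
    return support_sel, all_support, batch_idx, len(all_support)


def train_bpn(train_images, config: BPNTrainConfig, encoder=None,
              val_images=None):
    """Episodic training of the encoder under the prototype loss.

    Returns (encoder, history). The encoder weights are those with the
    best validation score (or the final weights when no validation set is
    given). Fully deterministic given the config seed.
    """
    if encoder is None:
        encoder = build_encoder(EncoderConfig(alpha=config.alpha,
                                              seed=config.seed))
    pool = _class_pool(train_images, config.classes)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(encoder.parameters(), lr=config.learning_rate)
    history = []
    best = (-np.inf, encoder.get_state())
    norm_cache = [normalize_patch(img.image) for img in train_images]

    def validate():
        ssel = {c: pool[c][:min(len(pool[c]), config.supports_per_class)]
                for c in config.classes}
        items = sorted({i for sel in ssel.values() for i in sel})
        sup = SupportSet([(train_images[i].image, train_images[i].mask)
                          for i in items])
        protos = compute_prototypes(sup, encoder, config.classes)
        return evaluate_pixel_accuracy(encoder, protos, val_images,
                                       config.classes)

    for ep in range(config.episodes):
        support_sel, sup_list, batch_idx, n_sup = _episode_batch(
            train_images, pool, rng, config)
        x = batch_input([norm_cache[i] for i in batch_idx])
        feats, _ = encoder.forward(x, training=True)
        _, _, fh, fw = feats.data.shape
        weights = np.stack([downsample_annotation(
            train_images[i].mask, (fh, fw)) for i in batch_idx])
        # prototypes from supports only
        sup_pos = {img_i: pos for pos, img_i in enumerate(sup_list)}
        sup_weights = np.zeros_like(weights)
        for c, sel in support_sel.items():
            for img_i in sel:
                p = sup_pos[int(img_i)]
                sup_weights[p, c] = weights[p, c]
        protos, _ = _prototype_tensors(feats, sup_weights, config.classes)
        scores = nn.proto_scores(feats, protos)
        targets = weights[:, list(config.classes)]
        qmask = np.zeros(len(batch_idx))
        qmask[n_sup:] = 1.0
        loss = corel_pixel_loss(scores, targets, config.gamma, qmask)
        opt.zero_grad()
        nn.backward(loss)
        opt.step()
        row = {"episode": ep + 1, "loss": float(loss.data),
               "val_score": np.nan}
        if val_images and (ep + 1) % config.validate_every == 0:
            row["val_score"] = validate()
            if row["val_score"] > best[0]:
                best = (row["val_score"], encoder.get_state())
        history.append(row)

    if config.episodes and val_images:
        if (history[-1]["episode"] % config.validate_every) != 0:
            score = validate()
            history[-1]["val_score"] = score
            if score > best[0]:
                best = (score, encoder.get_state())
        if best[0] > -np.inf:
            encoder.set_state(best[1])
    return encoder, pd.DataFrame(
        history, columns=["episode", "loss", "val_score"])


# ------------------------------------------------------ evaluation runs

def eval_protocol_bpn(encoders, support_images, test_images, ns: int = 100,
                      draws: int = 10, seed: int = 0,
                      classes: tuple = PREDICTED_CLASSES):
    """Multi-model, multi-support-draw evaluation.

    For each encoder and each of ``draws`` support draws, ``ns`` support
    patches are sampled, prototypes computed and the test set evaluated;
    the table reports mean and SD of the overall metrics across all runs.
    A draw missing some class is resampled (and logged).
    """
    from .seg_eval import accumulate_confusion, metrics_from_confusion
    if ns < 1 or draws < 1:
        raise ValueError("ns and draws must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for m_i, enc in enumerate(encoders):
        for d in range(draws):
            for attempt in range(100):
                idx = rng.choice(len(support_images), size=ns,
                                 replace=len(support_images) < ns)
                sup = SupportSet([(support_images[i].image,
                                   support_images[i].mask) for i in idx])
                if set(classes) <= sup.classes_present:
                    break
                logger.info("support draw missing a class; resampling "
                            "(model %d, draw %d, attempt %d)",
                            m_i, d, attempt + 1)
            else:
                raise ValueError("could not draw supports covering all "
                                 "classes")
            protos = compute_prototypes(sup, enc, classes)
            cm = None
            for img in test_images:
                res = segment_query(img.image, protos, enc, classes)
                cm = accumulate_confusion(img.mask, res.labels, cm)
            overall = metrics_from_confusion(cm)["overall"]
            rows.append({"model": m_i, "draw": d, **overall})
    runs = pd.DataFrame(rows)
    metrics = [c for c in runs.columns if c not in ("model", "draw")]
    summary = pd.DataFrame({
        "mean": runs[metrics].mean(),
        "sd": runs[metrics].std(ddof=1) if len(runs) > 1
        else pd.Series(0.0, index=metrics)})
    return summary, runs
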