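import numpy as np
import pandas as pd
import pytest

from tsrseg import nn
from tsrseg.bpn import (BPNTrainConfig, PrototypeSet, SupportSet,
                        compute_prototypes, corel_pixel_loss,
                        downsample_annotation, eval_protocol_bpn,
                        segment_query, similarity, train_bpn)
from tsrseg.encoder import SmallEncoderConfig, build_small_encoder

from stubs import ConstantEncoder, PoolEncoder


# ------------------------------------------------------- downsampling

class TestDownsampleAnnotation:
    def test_uniform_mask(self):
        w = downsample_annotation(np.zeros((64, 64), dtype=int), (4, 4))
        assert np.allclose(w[0], 1.0)
        assert np.allclose(w[1:], 0.0)

    def test_aligned_halves_no_mixed_cells(self):
        m = np.zeros((64, 64), dtype=int)
        m[:, 32:] = 1
        w = downsample_annotation(m, (4, 4))
        assert set(np.unique(w[:2])) == {0.0, 1.0}

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 6, (48, 48))
        w = downsample_annotation(m, (3, 3))
        for c in range(6):
            for i in range(3):
                for j in range(3):
                    cell = m[16 * i:16 * (i + 1), 16 * j:16 * (j + 1)]
                    assert w[c, i, j] == pytest.approx(
                        (cell == c).sum() / 256, abs=1e-12)
        assert np.allclose(w.sum(axis=0), 1.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            downsample_annotation(np.zeros((65, 64), dtype=int), (4, 4))


# -------------------------------------------------------- similarity

def test_similarity_examples():
    assert similarity([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert similarity([3.0, 4.0], [0.0, 0.0]) == -12.5
    with pytest.raises(ValueError):
        similarity([1.0], [1.0, 2.0])


def test_similarity_random_oracle():
    rng = np.random.default_rng(1)
    for _ in range(10):
        x, p = rng.normal(size=(2, 7))
        expected = -0.5 * sum((xi - pi) ** 2 for xi, pi in zip(x, p))
        assert similarity(x, p) == pytest.approx(expected, abs=1e-10)


# -------------------------------------------------------- prototypes

def _random_support(rng, size=64, classes=(0, 1, 2)):
    img = rng.integers(0, 255, (size, size, 3)).astype(np.uint8)
    mask = rng.choice(classes, size=(size, size))
    return img, mask


def test_prototype_constant_encoder():
    u = np.array([2.0, -1.0, 0.5])
    enc = ConstantEncoder(u)
    img = np.zeros((64, 64, 3), dtype=np.uint8)
    sup = SupportSet([(img, np.full((64, 64), 2, dtype=int))])
    protos = compute_prototypes(sup, enc, classes=(2,))
    assert np.allclose(protos.prototypes[2], u)


def test_prototype_is_mean_over_supports():
    """Two supports with per-support vectors a and b give (a+b)/2."""
    rng = np.random.default_rng(2)
    enc = PoolEncoder(output_stride=16, out_channels=5, seed=1)
    items = [_random_support(rng, classes=(0,)) for _ in range(2)]
    sup = SupportSet(items)
    singles = [compute_prototypes(SupportSet([it]), enc, (0,))
               .prototypes[0] for it in items]
    both = compute_prototypes(sup, enc, (0,)).prototypes[0]
    assert np.allclose(both, (singles[0] + singles[1]) / 2, atol=1e-12)


def test_prototypes_match_masked_mean_oracle():
    """Brute-force recomputation over all cells, to 1e-10."""
    rng = np.random.default_rng(3)
    enc = PoolEncoder(output_stride=16, out_channels=4, seed=2)
    items = [_random_support(rng) for _ in range(3)]
    sup = SupportSet(items)
    protos = compute_prototypes(sup, enc, classes=(0, 1, 2))
    for c in (0, 1, 2):
        vectors = []
        for img, mask in items:
            feats = enc.features(img)        # (C, h, w)
            w = downsample_annotation(mask, feats.shape[1:])[c]
            if w.sum() == 0:
                continue
            num = np.zeros(feats.shape[0])
            for i in range(w.shape[0]):
                for j in range(w.shape[1]):
                    num += w[i, j] * feats[:, i, j]
            vectors.append(num / w.sum())
        expected = np.mean(vectors, axis=0)
        assert np.allclose(protos.prototypes[c], expected, atol=1e-10)


def test_prototypes_permutation_and_duplication_invariant():
    rng = np.random.default_rng(4)
    enc = PoolEncoder(output_stride=16, out_channels=3)
    items = [_random_support(rng) for _ in range(3)]
    p1 = compute_prototypes(SupportSet(items), enc, (0, 1, 2))
    p2 = compute_prototypes(SupportSet(items[::-1]), enc, (0, 1, 2))
    p3 = compute_prototypes(SupportSet(items + items), enc, (0, 1, 2))
    for c in (0, 1, 2):
        assert np.allclose(p1.prototypes[c], p2.prototypes[c], atol=1e-12)
        assert np.allclose(p1.prototypes[c], p3.prototypes[c], atol=1e-12)


def test_missing_class_error_lists_names():
    enc = ConstantEncoder(np.ones(2))
    img = np.zeros((64, 64, 3), dtype=np.uint8)
    sup = SupportSet([(img, np.zeros((64, 64), dtype=int))])
    with pytest.raises(ValueError, match="stroma"):
        compute_prototypes(sup, enc, classes=(0, 1))


# ------------------------------------------------------ segmentation

def test_segment_all_pixels_nearest_prototype():
    u = np.array([1.0, 2.0])
    enc = ConstantEncoder(u)
    protos = PrototypeSet(
        {0: u + 5, 1: u + 3, 2: u, 3: u - 4, 4: u + 9},
        {c: 1 for c in range(5)})
    res = segment_query(np.zeros((64, 64, 3), dtype=np.uint8), protos, enc)
    assert (res.labels == 2).all()


def test_segment_tie_breaks_to_lowest_class():
    u = np.array([0.0, 1.0])
    enc = ConstantEncoder(u)
    protos = PrototypeSet({0: u.copy(), 3: u.copy()}, {0: 1, 3: 1})
    res = segment_query(np.zeros((32, 32, 3), dtype=np.uint8), protos, enc,
                        classes=(0, 3))
    assert (res.labels == 0).all()


def test_segment_missing_prototype_errors():
    enc = ConstantEncoder(np.zeros(2))
    protos = PrototypeSet({0: np.zeros(2)}, {0: 1})
    with pytest.raises(ValueError, match="missing"):
        segment_query(np.zeros((32, 32, 3), dtype=np.uint8), protos, enc,
                      classes=(0, 1))


def test_cell_labels_match_exhaustive_argmax():
    rng = np.random.default_rng(5)
    enc = PoolEncoder(output_stride=16, out_channels=4, seed=5)
    img = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
    protos = PrototypeSet({c: rng.normal(size=4) for c in range(5)},
                          {c: 1 for c in range(5)})
    res = segment_query(img, protos, enc)
    feats = enc.features(img)
    for i in range(feats.shape[1]):
        for j in range(feats.shape[2]):
            sims = [similarity(feats[:, i, j], protos.prototypes[c])
                    for c in range(5)]
            assert res.cell_labels[i, j] == int(np.argmax(sims))


def test_segment_equivariant_to_class_relabeling():
    rng = np.random.default_rng(6)
    enc = PoolEncoder(output_stride=16, out_channels=4, seed=6)
    img = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
    vecs = {c: rng.normal(size=4) for c in range(5)}
    perm = {0: 3, 1: 4, 2: 0, 3: 1, 4: 2}
    p1 = PrototypeSet(vecs, {c: 1 for c in vecs})
    p2 = PrototypeSet({perm[c]: v for c, v in vecs.items()},
                      {c: 1 for c in vecs})
    r1 = segment_query(img, p1, enc)
    r2 = segment_query(img, p2, enc)
    relabeled = np.vectorize(perm.get)(r1.labels)
    assert np.array_equal(relabeled, r2.labels)


# -------------------------------------------------------------- loss

def _loss_inputs(rng, n=2, k=3, h=4, w=4):
    scores = nn.Tensor(rng.normal(size=(n, k, h, w)))
    weights = rng.dirichlet(np.ones(k + 1), size=(n, h, w))
    targets = weights[..., :k].transpose(0, 3, 1, 2)  # leftover = artifact
    return scores, targets


def test_corel_gamma_zero_is_cross_entropy():
    rng = np.random.default_rng(7)
    scores, targets = _loss_inputs(rng)
    loss = corel_pixel_loss(scores, targets, gamma=0.0)
    # hand-rolled pixel-wise CE with fractional labels
    s = scores.data
    logp = s - np.log(np.exp(s).sum(axis=1, keepdims=True))
    labeled = targets.sum(axis=1)
    frac = targets / labeled[:, None]
    expected = ((-(frac * logp).sum(axis=1)) * labeled).sum() / labeled.sum()
    assert loss.data == pytest.approx(expected, abs=1e-12)


def test_corel_matches_two_term_oracle():
    rng = np.random.default_rng(8)
    scores, targets = _loss_inputs(rng)
    gamma = 0.5
    loss = corel_pixel_loss(scores, targets, gamma)
    s = scores.data
    logp = s - np.log(np.exp(s).sum(axis=1, keepdims=True))
    labeled = targets.sum(axis=1)
    frac = targets / labeled[:, None]
    ce = ((-(frac * logp).sum(axis=1)) * labeled).sum() / labeled.sum()
    true_cls = targets.argmax(axis=1)
    dists = []
    for nidx in range(s.shape[0]):
        for i in range(s.shape[2]):
            for j in range(s.shape[3]):
                if labeled[nidx, i, j] > 0:
                    dists.append(-2 * s[nidx, true_cls[nidx, i, j], i, j])
    expected = ce + gamma * np.mean(dists)
    assert loss.data == pytest.approx(expected, abs=1e-10)


def test_corel_attainable_minimum_tends_to_zero():
    """Features on their prototypes, wrong-class similarity -> -inf."""
    n, k, h, w = 1, 3, 2, 2
    true_cls = np.array([[[0, 1], [2, 0]]])
    big = 1e4
    s = np.full((n, k, h, w), -big)
    for i in range(h):
        for j in range(w):
            s[0, true_cls[0, i, j], i, j] = 0.0  # feature == prototype
    targets = np.eye(k)[true_cls].transpose(0, 3, 1, 2)
    loss = corel_pixel_loss(nn.Tensor(s), targets, gamma=0.5)
    assert 0 <= loss.data < 1e-8


def test_corel_rejects_nan_scores():
    s = nn.Tensor(np.full((1, 2, 2, 2), np.nan))
    t = np.ones((1, 2, 2, 2)) / 2
    with pytest.raises(ValueError, match="finite"):
        corel_pixel_loss(s, t, 0.5)


# ---------------------------------------------------------- training

def _tiny_images(dataset):
    return dataset.split_images("train")


def test_train_zero_episodes_keeps_weights(dataset):
    enc = build_small_encoder(SmallEncoderConfig(seed=3))
    before = [p.data.copy() for p in enc.parameters()]
    cfg = BPNTrainConfig(episodes=0, supports_per_class=2,
                         queries_per_episode=1, seed=0, classes=(0, 1, 4))
    enc, history = train_bpn(_tiny_images(dataset), cfg, encoder=enc)
    assert history.empty
    for p, b in zip(enc.parameters(), before):
        assert np.array_equal(p.data, b)


def test_train_deterministic_history(dataset):
    cfg = BPNTrainConfig(episodes=4, supports_per_class=2,
                         queries_per_episode=1, seed=5, classes=(0, 1, 4))
    hists = []
    for _ in range(2):
        enc = build_small_encoder(SmallEncoderConfig(seed=3))
        _, h = train_bpn(_tiny_images(dataset), cfg, encoder=enc)
        hists.append(h)
    pd.testing.assert_frame_equal(hists[0], hists[1])


def test_train_rejects_missing_class(dataset):
    cfg = BPNTrainConfig(episodes=1, classes=(0, 1, 2), seed=0)
    with pytest.raises(ValueError, match="necrosis"):
        train_bpn(_tiny_images(dataset), cfg,
                  encoder=build_small_encoder(SmallEncoderConfig()))


def test_untrained_prototypes_above_chance(bpn_run):
    # 3 balanced classes -> chance ~1/3; frozen random encoder must beat it
    assert bpn_run.accuracy_untrained > 0.45


def test_training_improves_heldout_accuracy(bpn_run):
    assert bpn_run.accuracy_trained > bpn_run.accuracy_untrained


# ------------------------------------------------------ eval protocol

def test_eval_protocol_single_run_and_aggregation(dataset):
    enc = build_small_encoder(SmallEncoderConfig(seed=1))
    train = dataset.split_images("train")
    test = dataset.split_images("test")
    summary1, runs1 = eval_protocol_bpn([enc], train, test, ns=6, draws=1,
                                        seed=3, classes=(0, 1, 4))
    assert len(runs1) == 1
    assert np.allclose(summary1["mean"].to_numpy(),
                       runs1.drop(columns=["model", "draw"])
                       .iloc[0].to_numpy())

    enc2 = build_small_encoder(SmallEncoderConfig(seed=2))
    summary, runs = eval_protocol_bpn([enc, enc2], train, test, ns=6,
                                      draws=2, seed=3, classes=(0, 1, 4))
    assert len(runs) == 4  # models x draws
    metrics = runs.drop(columns=["model", "draw"])
    assert np.allclose(summary["mean"].to_numpy(),
                       metrics.mean().to_numpy())
    assert np.allclose(summary["sd"].to_numpy(),
                       metrics.std(ddof=1).to_numpy())
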