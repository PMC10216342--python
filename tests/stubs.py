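"""Deterministic stub encoders for unit tests."""
import numpy as np

from tsrseg import nn


class PoolEncoder:
    """Block-mean pooling of the input, optionally randomly projected.

    Cheap, exactly recomputable by brute force, and shaped like a real
    encoder output (N, C, H/stride, W/stride).
    """

    def __init__(self, output_stride=16, out_channels=3, seed=0):
        self.output_stride = output_stride
        if out_channels == 3:
            self.proj = None
        else:
            rng = np.random.default_rng(seed)
            self.proj = rng.normal(size=(out_channels, 3))
        self.out_channels = out_channels
        self.skip_channels = {}

    def __call__(self, x, training=False):
        d = x.data
        n, c, h, w = d.shape
        s = self.output_stride
        pooled = d.reshape(n, c, h // s, s, w // s, s).mean(axis=(3, 5))
        if self.proj is not None:
            pooled = np.einsum("oc,nchw->nohw", self.proj, pooled)
        return nn.Tensor(pooled, requires_grad=False)

    def features(self, patch):
        from tsrseg.encoder import as_input, normalize_patch
        return self(as_input(normalize_patch(patch))).data[0]


class ConstantEncoder:
    """Stub emitting the same feature vector at every cell."""

    def __init__(self, vector, output_stride=16):
        self.vector = np.asarray(vector, dtype=float)
        self.output_stride = output_stride
        self.out_channels = len(self.vector)

    def __call__(self, x, training=False):
        n, _, h, w = x.data.shape
        s = self.output_stride
        out = np.tile(self.vector[None, :, None, None],
                      (n, 1, h // s, w // s))
        return nn.Tensor(out, requires_grad=False)

    def features(self, patch):
        h, w = patch.shape[:2]
        s = self.output_stride
        return np.tile(self.vector[:, None, None], (1, h // s, w // s))
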