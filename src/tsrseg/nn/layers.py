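"""Layer modules (parameter containers) for the NumPy network core."""
from __future__ import annotations

import numpy as np

from .tensor import Tensor, batch_norm, conv2d, depthwise_conv2d


class Module:
    """Base class: tracks child modules and parameters by attribute."""

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor):
                        out.append(item)
        return out

    def state_arrays(self) -> list[np.ndarray]:
        """All mutable arrays (parameters + BN running stats), in order."""
        arrays = [p.data for p in self.parameters()]
        for bn in self._bn_modules():
            arrays.extend([bn.state["mean"], bn.state["var"]])
        return arrays

    def _bn_modules(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, BatchNorm2d):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v._bn_modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item._bn_modules())
        return out

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError("state length mismatch")
        for dst, src in zip(arrays, state):
            if dst.shape != np.asarray(src).shape:
                raise ValueError("state shape mismatch")
            dst[...] = src


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, scale, size=(c_out, c_in, k, k)))
        self.b = Tensor(np.zeros(c_out)) if bias else None
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class DepthwiseConv2d(Module):
    def __init__(self, c: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (k * k))
        self.w = Tensor(rng.normal(0.0, scale, size=(c, k, k)))
        self.stride = stride
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.w, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c))
        self.beta = Tensor(np.zeros(c))
        self.state = {"mean": np.zeros(c), "var": np.ones(c)}
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return batch_norm(x, self.gamma, self.beta, self.state,
                          training, self.momentum, self.eps)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
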