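"""Layers and parameter containers built on the autodiff core."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out,
                   dtype=np.float32) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(dtype),
                  requires_grad=True)


def zeros_param(shape, dtype=np.float32) -> Tensor:
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


class BatchNorm:
    """Batch normalization over the given axes with running statistics.

    ``param_shape`` must broadcast against the input; ``axes`` are the axes
    averaged over (everything except the feature axis).
    """

    def __init__(self, param_shape, axes, momentum=0.9, eps=1e-3,
                 dtype=np.float32):
        self.gamma = Tensor(np.ones(param_shape, dtype=dtype), requires_grad=True)
        self.beta = zeros_param(param_shape, dtype=dtype)
        self.axes = tuple(axes)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(param_shape, dtype=dtype)
        self.running_var = np.ones(param_shape, dtype=dtype)

    def parameters(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            out, mu, var = ag.batchnorm_train(x, self.gamma, self.beta,
                                              self.axes, self.eps)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
            return out
        # inference: single fused affine with the running statistics
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.gamma.data * inv
        shift = self.beta.data - self.running_mean * scale
        return ag.add(ag.mul(x, Tensor(scale)), Tensor(shift))


class Dropout:
    """Inverted dropout; identity in inference mode."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def __call__(self, x: Tensor, training: bool,
                 rng: np.random.Generator | None = None) -> Tensor:
        if not training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = (rng.random(x.shape) >= self.p).astype(x.data.dtype)
        return ag.mul(x, Tensor(keep / (1.0 - self.p)))


class Dense:
    def __init__(self, rng, n_in, n_out, dtype=np.float32):
        self.w = glorot_uniform(rng, (n_in, n_out), n_in, n_out, dtype)
        self.b = zeros_param((n_out,), dtype)

    def parameters(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.dot_last(x, self.w), self.b)
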