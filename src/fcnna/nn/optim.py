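"""Adam optimizer and weight constraints."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class MaxNorm:
    """Renormalize a kernel so its norm along ``axis`` stays <= ``max_value``.

    Applied after every optimizer step, mirroring the max-norm option on the
    depthwise spatial convolution (each electrode-spanning kernel is kept at
    unit norm or below).
    """

    def __init__(self, param: Tensor, axis: int, max_value: float = 1.0):
        self.param = param
        self.axis = axis
        self.max_value = max_value

    def apply(self):
        w = self.param.data
        norms = np.sqrt((w * w).sum(axis=self.axis, keepdims=True))
        factor = np.minimum(1.0, self.max_value / np.maximum(norms, 1e-12))
        self.param.data = w * factor


class Adam:
    """Adam with framework-default moments (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, params, lr=9e-4, beta1=0.9, beta2=0.999, eps=1e-7,
                 constraints=()):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.constraints = list(constraints)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            p.data = p.data - lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)
        for c in self.constraints:
            c.apply()
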