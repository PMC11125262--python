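"""Convolutional Block Attention Module (CBAM).

Channel attention gates each feature map by a sigmoid score computed from
global average- and max-pooled descriptors passed through a shared bottleneck
MLP; spatial attention gates each temporal position from the
channel-wise average/max planes convolved with a same-padded kernel:

    Mc(F)  = sigma(MLP(avgpool(F)) + MLP(maxpool(F)))
    Ms(F') = sigma(conv_k([avgpool_c(F'); maxpool_c(F')]))
    F'  = Mc (x) F          (broadcast over H x W)
    F'' = Ms (x) F'         (broadcast over the filter axis)

Here feature maps have height 1 (the electrode axis was collapsed by the
depthwise stage), so the spatial kernel is 1 x ``spatial_kernel``.  The
functional API below works on single (H, W, C) numpy maps and is the
reference the differentiable module (:class:`CBAMModule`) is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import autograd as ag
from .errors import ConfigurationError


@dataclass
class CBAMConfig:
    """Attention hyperparameters.

    ``reduction_ratio`` sets the bottleneck width ``max(C // r, 1)`` of the
    shared MLP (r=16 follows the original CBAM design); ``spatial_kernel``
    is the width of the spatial-attention convolution (7 in this model).
    ``mlp_activation`` applies to the bottleneck hidden layer.
    """

    reduction_ratio: int = 16
    spatial_kernel: int = 7
    mlp_activation: str = "relu"

    def __post_init__(self):
        if self.reduction_ratio < 1:
            raise ConfigurationError("reduction_ratio must be >= 1")
        if self.spatial_kernel % 2 != 1:
            raise ConfigurationError("spatial_kernel must be odd")

    def mlp_hidden(self, n_filters: int) -> int:
        return max(n_filters // self.reduction_ratio, 1)


@dataclass
class CBAMParams:
    """Weights of one CBAM block (numpy arrays).

    ``w1``/``b1`` and ``w2``/``b2`` are the shared bottleneck MLP
    (C -> hidden -> C); ``conv_w`` has shape (2 * spatial_kernel,) stacking
    the kernel applied to the average plane then the max plane; ``conv_b``
    is its scalar bias.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    conv_w: np.ndarray
    conv_b: float

    @classmethod
    def zeros(cls, n_filters: int, cfg: CBAMConfig) -> "CBAMParams":
        h = cfg.mlp_hidden(n_filters)
        return cls(w1=np.zeros((n_filters, h)), b1=np.zeros(h),
                   w2=np.zeros((h, n_filters)), b2=np.zeros(n_filters),
                   conv_w=np.zeros(2 * cfg.spatial_kernel), conv_b=0.0)

    @classmethod
    def random(cls, n_filters: int, cfg: CBAMConfig,
               rng: np.random.Generator, scale: float = 0.3) -> "CBAMParams":
        h = cfg.mlp_hidden(n_filters)
        return cls(w1=rng.normal(0, scale, (n_filters, h)),
                   b1=rng.normal(0, scale, h),
                   w2=rng.normal(0, scale, (h, n_filters)),
                   b2=rng.normal(0, scale, n_filters),
                   conv_w=rng.normal(0, scale, 2 * cfg.spatial_kernel),
                   conv_b=float(rng.normal(0, scale)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _mlp(v: np.ndarray, p: CBAMParams, cfg: CBAMConfig) -> np.ndarray:
    h = v @ p.w1 + p.b1
    if cfg.mlp_activation == "relu":
        h = np.maximum(h, 0.0)
    return h @ p.w2 + p.b2


def channel_attention(F: np.ndarray, params: CBAMParams,
                      cfg: CBAMConfig) -> np.ndarray:
    """Channel attention vector Mc of length C for one (H, W, C) map."""
    F = np.asarray(F, dtype=float)
    avg = F.mean(axis=(0, 1))
    mx = F.max(axis=(0, 1))
    return _sigmoid(_mlp(avg, params, cfg) + _mlp(mx, params, cfg))


def spatial_attention(F_prime: np.ndarray, params: CBAMParams,
                      cfg: CBAMConfig) -> np.ndarray:
    """Spatial attention map Ms of shape (H, W) for one (H, W, C) map."""
    Fp = np.asarray(F_prime, dtype=float)
    H, W, _ = Fp.shape
    avg = Fp.mean(axis=2)
    mx = Fp.max(axis=2)
    k = cfg.spatial_kernel
    pl = (k - 1) // 2
    out = np.full((H, W), float(params.conv_b))
    # same-padded 1 x k convolution over the two stacked planes
    avg_p = np.pad(avg, ((0, 0), (pl, k - 1 - pl)))
    mx_p = np.pad(mx, ((0, 0), (pl, k - 1 - pl)))
    for j in range(k):
        out += params.conv_w[j] * avg_p[:, j:j + W]
        out += params.conv_w[k + j] * mx_p[:, j:j + W]
    return _sigmoid(out)


def apply_cbam(F: np.ndarray, params: CBAMParams,
               cfg: CBAMConfig) -> np.ndarray:
    """Refined map F'' = Ms (x) (Mc (x) F); shape preserved."""
    F = np.asarray(F, dtype=float)
    Mc = channel_attention(F, params, cfg)
    F_prime = F * Mc[None, None, :]
    Ms = spatial_attention(F_prime, params, cfg)
    return F_prime * Ms[:, :, None]


class CBAMModule:
    """Differentiable CBAM over batched (B, C_f, W) feature tensors."""

    def __init__(self, n_filters: int, cfg: CBAMConfig,
                 rng: np.random.Generator, dtype=np.float32):
        self.cfg = cfg
        self.n_filters = n_filters
        h = cfg.mlp_hidden(n_filters)
        k = cfg.spatial_kernel
        self.w1 = nn.glorot_uniform(rng, (n_filters, h), n_filters, h, dtype)
        self.b1 = nn.zeros_param((h,), dtype)
        self.w2 = nn.glorot_uniform(rng, (h, n_filters), h, n_filters, dtype)
        self.b2 = nn.zeros_param((n_filters,), dtype)
        self.conv_w = nn.glorot_uniform(rng, (2 * k, 1), 2 * k, 1, dtype)
        self.conv_b = nn.zeros_param((1,), dtype)

    def parameters(self):
        return [self.w1, self.b1, self.w2, self.b2, self.conv_w, self.conv_b]

    def _mlp(self, v):
        h = ag.add(ag.dot_last(v, self.w1), self.b1)
        if self.cfg.mlp_activation == "relu":
            h = ag.relu(h)
        return ag.add(ag.dot_last(h, self.w2), self.b2)

    def __call__(self, x):
        B, Cf, W = x.shape
        avg = ag.reshape(ag.mean(x, axes=(2,)), (B, Cf))
        mx = ag.reshape(ag.amax(x, axes=(2,)), (B, Cf))
        mc = ag.sigmoid(ag.add(self._mlp(avg), self._mlp(mx)))
        x_prime = ag.mul(x, ag.reshape(mc, (B, Cf, 1)))

        savg = ag.mean(x_prime, axes=(1,))          # (B, 1, W)
        smax = ag.amax(x_prime, axes=(1,))
        planes = ag.concat([savg, smax], axis=1)     # (B, 2, W)
        k = self.cfg.spatial_kernel
        win = ag.unfold_last(planes, k)              # (B, 2, W, k)
        win = ag.moveaxis(win, 1, 2)                 # (B, W, 2, k)
        win = ag.reshape(win, (B, W, 2 * k))
        ms = ag.sigmoid(ag.add(ag.dot_last(win, self.conv_w), self.conv_b))
        ms = ag.moveaxis(ms, 2, 1)                   # (B, 1, W)
        return ag.mul(x_prime, ms)

    def export_params(self) -> CBAMParams:
        """Numpy snapshot in the functional-API layout."""
        return CBAMParams(
            w1=self.w1.data.astype(float), b1=self.b1.data.astype(float),
            w2=self.w2.data.astype(float), b2=self.b2.data.astype(float),
            conv_w=self.conv_w.data[:, 0].astype(float),
            conv_b=float(self.conv_b.data[0]))
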