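"""The dual-branch convolutional motor-imagery classifier.

Each branch follows the EEGNet-style recipe — a temporal convolution
(F1 filters, 1 x KE1, same padding), a depthwise convolution spanning all
electrodes (depth multiplier D, max-norm 1), and a separable convolution
(F2 = F1 x D pointwise filters, 1 x KE2) — with batch normalization, ELU,
average pooling (1x4 then 1x8) and dropout 0.5 between stages, and a CBAM
attention block on its output.  The two branches see the same input but use
different temporal resolutions (defaults: F1=96, D=2, KE1=60 versus F1=16,
D=1, KE1=64); their attended feature maps are concatenated along the filter
axis, flattened and classified by a dense softmax layer.

For the default input (C=22 electrodes, T=1125 samples) the wide branch
enters its attention block as a 1 x 35 x 192 map and the fused feature
vector has length 35 x (192 + 16) = 7280.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import autograd as ag
from .attention import CBAMConfig, CBAMModule
from .errors import ConfigurationError


@dataclass
class ConvBranchConfig:
    """Hyperparameters of one convolutional branch."""

    F1: int = 96
    D: int = 2
    KE1: int = 60
    KE2: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout_p: float = 0.5
    activation: str = "ELU"

    def __post_init__(self):
        for name in ("F1", "D", "KE1", "KE2", "pool1", "pool2"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigurationError("dropout_p must be in [0, 1)")
        if self.activation != "ELU":
            raise ConfigurationError("only ELU activation is supported")

    @property
    def F2(self) -> int:
        """Pointwise filter count, F2 = F1 x D."""
        return self.F1 * self.D


def default_branch_a() -> ConvBranchConfig:
    return ConvBranchConfig(F1=96, D=2, KE1=60)


def default_branch_b() -> ConvBranchConfig:
    return ConvBranchConfig(F1=16, D=1, KE1=64)


@dataclass
class ModelConfig:
    """Full model description: two branches over a (C, T) input, N classes."""

    C: int = 22
    T: int = 1125
    N: int = 4
    branch_a: ConvBranchConfig = field(default_factory=default_branch_a)
    branch_b: ConvBranchConfig = field(default_factory=default_branch_b)
    cbam: CBAMConfig = field(default_factory=CBAMConfig)

    def __post_init__(self):
        if self.C < 1:
            raise ConfigurationError("C must be >= 1")
        if self.N < 2:
            raise ConfigurationError("N must be >= 2")
        for br in (self.branch_a, self.branch_b):
            if self.T < br.pool1 * br.pool2:
                raise ConfigurationError(
                    f"T={self.T} too short for the pooling cascade "
                    f"{br.pool1}x{br.pool2}")

    def fused_width(self) -> int:
        wa = self.T // self.branch_a.pool1 // self.branch_a.pool2
        wb = self.T // self.branch_b.pool1 // self.branch_b.pool2
        if wa != wb:
            raise ConfigurationError(
                "branches disagree on pooled width; use equal pool products")
        return wa

    def flat_features(self) -> int:
        return self.fused_width() * (self.branch_a.F2 + self.branch_b.F2)


def output_shapes(config: ModelConfig):
    """Layer-by-layer output shapes of the model graph.

    Widths use floor division, matching the average-pooling layers.
    """
    shapes = []
    for tag, br in (("a", config.branch_a), ("b", config.branch_b)):
        C, T = config.C, config.T
        w1 = T // br.pool1
        w2 = w1 // br.pool2
        shapes += [
            (f"branch_{tag}/input", (C, T)),
            (f"branch_{tag}/temporal_conv", (C, T, br.F1)),
            (f"branch_{tag}/depthwise_conv", (1, T, br.F1 * br.D)),
            (f"branch_{tag}/avgpool1", (1, w1, br.F1 * br.D)),
            (f"branch_{tag}/separable_conv", (1, w1, br.F2)),
            (f"branch_{tag}/avgpool2", (1, w2, br.F2)),
            (f"branch_{tag}/cbam", (1, w2, br.F2)),
        ]
    w = config.fused_width()
    shapes += [
        ("concatenate", (1, w, config.branch_a.F2 + config.branch_b.F2)),
        ("flatten", (w * (config.branch_a.F2 + config.branch_b.F2),)),
        ("dense", (config.N,)),
    ]
    return shapes


class _ConvBranch:
    """One branch; internal tensor layout is (batch, filters, width)."""

    def __init__(self, cfg: ConvBranchConfig, C: int, cbam_cfg: CBAMConfig,
                 rng: np.random.Generator, dtype=np.float32):
        self.cfg = cfg
        F1, D, F2 = cfg.F1, cfg.D, cfg.F2
        self.w_temporal = nn.glorot_uniform(
            rng, (cfg.KE1, F1), cfg.KE1, F1, dtype)
        self.bn1 = nn.BatchNorm((1, 1, 1, F1), axes=(0, 1, 2), dtype=dtype)
        self.w_depthwise = nn.glorot_uniform(rng, (F1, C, D), C, D, dtype)
        self.bn2 = nn.BatchNorm((1, F1 * D, 1), axes=(0, 2), dtype=dtype)
        self.drop1 = nn.Dropout(cfg.dropout_p)
        self.w_sep_depth = nn.glorot_uniform(
            rng, (F1 * D, cfg.KE2), cfg.KE2, 1, dtype)
        self.w_sep_point = nn.glorot_uniform(rng, (F1 * D, F2), F1 * D, F2,
                                             dtype)
        self.bn3 = nn.BatchNorm((1, F2, 1), axes=(0, 2), dtype=dtype)
        self.drop2 = nn.Dropout(cfg.dropout_p)
        self.cbam = CBAMModule(F2, cbam_cfg, rng, dtype)

    def parameters(self):
        return ([self.w_temporal] + self.bn1.parameters()
                + [self.w_depthwise] + self.bn2.parameters()
                + [self.w_sep_depth, self.w_sep_point] + self.bn3.parameters()
                + self.cbam.parameters())

    def constraints(self):
        # max-norm 1 on each electrode-spanning depthwise kernel
        return [nn.MaxNorm(self.w_depthwise, axis=1, max_value=1.0)]

    def __call__(self, x, training, rng):
        cfg = self.cfg
        B = x.shape[0]
        h = ag.unfold_last(x, cfg.KE1)                 # (B, C, T, KE1)
        h = ag.dot_last(h, self.w_temporal)            # (B, C, T, F1)
        h = self.bn1(h, training)
        h = ag.spatial_collapse(h, self.w_depthwise)   # (B, F1, D, T)
        h = ag.reshape(h, (B, cfg.F1 * cfg.D, x.shape[2]))
        h = self.bn2(h, training)
        h = ag.elu(h)
        h = ag.avgpool_last(h, cfg.pool1)
        h = self.drop1(h, training, rng)
        h = ag.unfold_last(h, cfg.KE2)                 # (B, F1D, W, KE2)
        h = ag.per_filter_dot(h, self.w_sep_depth)     # depthwise temporal
        h = ag.pointwise(h, self.w_sep_point)          # (B, F2, W)
        h = self.bn3(h, training)
        h = ag.elu(h)
        h = ag.avgpool_last(h, cfg.pool2)
        h = self.drop2(h, training, rng)
        return self.cbam(h)                            # (B, F2, W//pool2)


class FCNNAModel:
    """Trainable dual-branch classifier. Build via :func:`build_model`."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.branch_a = _ConvBranch(config.branch_a, config.C, config.cbam,
                                    rng, dtype)
        self.branch_b = _ConvBranch(config.branch_b, config.C, config.cbam,
                                    rng, dtype)
        self.dense = nn.Dense(rng, config.flat_features(), config.N, dtype)

    def parameters(self):
        return (self.branch_a.parameters() + self.branch_b.parameters()
                + self.dense.parameters())

    def constraints(self):
        return self.branch_a.constraints() + self.branch_b.constraints()

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 3 or X.shape[1] != self.config.C or \
                X.shape[2] != self.config.T:
            raise ConfigurationError(
                f"expected input of shape (batch, {self.config.C}, "
                f"{self.config.T}), got {X.shape}")
        return X.astype(self.dtype)

    def forward(self, x: nn.Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> nn.Tensor:
        ha = self.branch_a(x, training, rng)
        hb = self.branch_b(x, training, rng)
        h = ag.concat([ha, hb], axis=1)                # (B, F2a+F2b, W)
        h = ag.reshape(h, (h.shape[0], -1))
        return self.dense(h)                           # logits (B, N)

    def loss(self, X: np.ndarray, onehot: np.ndarray,
             rng: np.random.Generator) -> nn.Tensor:
        x = nn.Tensor(self._check_input(X))
        logits = self.forward(x, training=True, rng=rng)
        return ag.softmax_cross_entropy(logits, onehot.astype(self.dtype))

    def predict_proba(self, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
        # batch 32 keeps the unfold workspace inside cache; larger inference
        # batches are markedly slower on one core
        """Class probabilities (trials x N); deterministic (inference mode)."""
        X = self._check_input(X)
        out = []
        for i in range(0, len(X), batch_size):
            x = nn.Tensor(X[i:i + batch_size])
            logits = self.forward(x, training=False)
            out.append(ag.softmax(logits).data)
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class labels in 1..N."""
        return self.predict_proba(X).argmax(axis=1) + 1

    # Weight snapshots ---------------------------------------------
    def get_weights(self):
        state = [p.data.copy() for p in self.parameters()]
        running = []
        for br in (self.branch_a, self.branch_b):
            for bn in (br.bn1, br.bn2, br.bn3):
                running.append((bn.running_mean.copy(), bn.running_var.copy()))
        return state, running

    def set_weights(self, snapshot):
        state, running = snapshot
        for p, w in zip(self.parameters(), state):
            p.data = w.copy()
        it = iter(running)
        for br in (self.branch_a, self.branch_b):
            for bn in (br.bn1, br.bn2, br.bn3):
                mean, var = next(it)
                bn.running_mean = mean.copy()
                bn.running_var = var.copy()

    def save(self, path):
        payload = {"config": self.config, "weights": self.get_weights()}
        Path(path).write_bytes(pickle.dumps(payload))

    @classmethod
    def load(cls, path) -> "FCNNAModel":
        payload = pickle.loads(Path(path).read_bytes())
        model = cls(payload["config"])
        model.set_weights(payload["weights"])
        return model

    def summary(self) -> str:
        """Text dump of the layer walk (for diffing architectures)."""
        lines = [f"{name:32s} {shape}" for name, shape in
                 output_shapes(self.config)]
        n_params = sum(p.data.size for p in self.parameters())
        lines.append(f"{'total parameters':32s} {n_params}")
        return "\n".join(lines)


def build_model(config: ModelConfig, seed: int = 0,
                dtype=np.float32) -> FCNNAModel:
    """Construct a trainable model from its configuration."""
    config.fused_width()  # raises if the branches are inconsistent
    return FCNNAModel(config, seed=seed, dtype=dtype)


def predict_proba(model: FCNNAModel, trials) -> np.ndarray:
    """Probability matrix for a TrialSet or raw (trials, C, T) array."""
    X = getattr(trials, "data", trials)
    return model.predict_proba(np.asarray(X))


def tiny_config(C: int, T: int, N: int = 4) -> ModelConfig:
    """A reduced-width configuration for desk-scale experiments.

    Keeps the full dual-branch + CBAM topology but shrinks filter counts and
    temporal kernels so training fits a single CPU.
    """
    return ModelConfig(
        C=C, T=T, N=N,
        branch_a=ConvBranchConfig(F1=8, D=2, KE1=31, KE2=8),
        branch_b=ConvBranchConfig(F1=4, D=1, KE1=33, KE2=8),
        cbam=CBAMConfig(reduction_ratio=4),
    )
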