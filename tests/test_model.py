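"""Architecture conformance: the layer-shape walk against an independent
floor-arithmetic oracle, forward-pass shapes, softmax behaviour, the
max-norm constraint and dropout semantics."""

import numpy as np
import pytest

from fcnna.attention import CBAMConfig
from fcnna.errors import ConfigurationError
from fcnna.model import (ConvBranchConfig, ModelConfig, build_model,
                         output_shapes, tiny_config)
from fcnna.nn import Adam
from fcnna.training import one_hot


def shape_walk_oracle(C, T, F1, D, pool1, pool2):
    """Hand floor-arithmetic through one branch, written independently of
    the model code: conv keeps (C, T, F1); the depthwise stage collapses
    electrodes to (1, T, F1*D); each pooling floor-divides the width."""
    w1 = T // pool1
    w2 = w1 // pool2
    return [(C, T), (C, T, F1), (1, T, F1 * D), (1, w1, F1 * D),
            (1, w1, F1 * D), (1, w2, F1 * D), (1, w2, F1 * D)]


@pytest.mark.parametrize("C,T", [(22, 1125), (22, 200), (6, 64), (3, 97)])
def test_output_shapes_match_floor_oracle(C, T):
    cfg = ModelConfig(C=C, T=T, N=4)
    shapes = dict(output_shapes(cfg))
    for tag, br in (("a", cfg.branch_a), ("b", cfg.branch_b)):
        oracle = shape_walk_oracle(C, T, br.F1, br.D, br.pool1, br.pool2)
        assert shapes[f"branch_{tag}/input"] == oracle[0]
        assert shapes[f"branch_{tag}/temporal_conv"] == oracle[1]
        assert shapes[f"branch_{tag}/depthwise_conv"] == oracle[2]
        assert shapes[f"branch_{tag}/avgpool1"] == oracle[3]
        assert shapes[f"branch_{tag}/separable_conv"] == oracle[4]
        assert shapes[f"branch_{tag}/avgpool2"] == oracle[5]
        assert shapes[f"branch_{tag}/cbam"] == oracle[6]
    w = T // 4 // 8
    f_total = cfg.branch_a.F2 + cfg.branch_b.F2
    assert shapes["concatenate"] == (1, w, f_total)
    assert shapes["flatten"] == (w * f_total,)
    assert shapes["dense"] == (4,)


def test_reference_dimensions():
    """Defaults with C=22, T=1125: 192 depthwise filters, CBAM input width
    35, fused feature vector 35 x (192 + 16) = 7280."""
    cfg = ModelConfig()
    shapes = dict(output_shapes(cfg))
    assert cfg.branch_a.F2 == 192
    assert shapes["branch_a/depthwise_conv"] == (1, 1125, 192)
    assert shapes["branch_a/cbam"] == (1, 35, 192)
    assert shapes["branch_b/cbam"] == (1, 35, 16)
    assert cfg.flat_features() == 7280
    assert shapes["dense"] == (4,)


def test_branch_defaults_match_reference():
    cfg = ModelConfig()
    assert (cfg.branch_a.F1, cfg.branch_a.D, cfg.branch_a.KE1) == (96, 2, 60)
    assert (cfg.branch_b.F1, cfg.branch_b.D, cfg.branch_b.KE1) == (16, 1, 64)
    assert cfg.branch_a.KE2 == cfg.branch_b.KE2 == 16
    assert cfg.branch_a.dropout_p == 0.5


def test_f2_is_f1_times_d():
    br = ConvBranchConfig(F1=7, D=3)
    assert br.F2 == 21


def test_forward_shapes_agree_with_walk(tiny_model_config, rng):
    model = build_model(tiny_model_config, seed=0)
    X = rng.normal(size=(5, 6, 64)).astype(np.float32)
    P = model.predict_proba(X)
    assert P.shape == (5, 4)
    # forward feature width equals the declared fused width
    assert dict(output_shapes(tiny_model_config))["flatten"] == \
        (tiny_model_config.flat_features(),)


def test_predict_proba_rows_normalized(tiny_model_config, rng):
    model = build_model(tiny_model_config, seed=1)
    X = rng.normal(size=(8, 6, 64))
    P = model.predict_proba(X)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-6)
    assert (P >= 0).all()


def test_inference_deterministic_and_duplicates_identical(tiny_model_config,
                                                          rng):
    model = build_model(tiny_model_config, seed=2)
    x = rng.normal(size=(1, 6, 64))
    X = np.concatenate([x, x, x])
    P = model.predict_proba(X)
    assert np.allclose(P[0], P[1]) and np.allclose(P[0], P[2])
    assert np.allclose(P, model.predict_proba(X))


def test_training_mode_forward_is_stochastic(tiny_model_config, rng):
    from fcnna.nn import Tensor
    model = build_model(tiny_model_config, seed=3)
    x = Tensor(rng.normal(size=(4, 6, 64)).astype(np.float32))
    a = model.forward(x, training=True, rng=np.random.default_rng(0)).data
    b = model.forward(x, training=True, rng=np.random.default_rng(1)).data
    assert not np.allclose(a, b), "dropout should differ across draws"


def test_shape_mismatch_raises(tiny_model_config, rng):
    model = build_model(tiny_model_config, seed=0)
    with pytest.raises(ConfigurationError, match="6, 64"):
        model.predict_proba(rng.normal(size=(2, 5, 64)))


def test_too_short_input_rejected():
    with pytest.raises(ConfigurationError):
        ModelConfig(C=4, T=16, N=4)  # below the 4 x 8 pooling cascade


def test_max_norm_constraint_after_steps(tiny_model_config, rng):
    """Every depthwise electrode kernel keeps norm <= 1 after optimization."""
    model = build_model(tiny_model_config, seed=4)
    X = rng.normal(size=(16, 6, 64)).astype(np.float32)
    onehot = one_hot(rng.integers(1, 5, 16), 4)
    opt = Adam(model.parameters(), lr=0.05, constraints=model.constraints())
    for _ in range(5):
        opt.zero_grad()
        loss = model.loss(X, onehot, rng)
        loss.backward()
        opt.step()
    for br in (model.branch_a, model.branch_b):
        w = br.w_depthwise.data
        norms = np.sqrt((w * w).sum(axis=1))
        assert (norms <= 1.0 + 1e-6).all()
    # the aggressive learning rate actually pushed kernels to the boundary,
    # so the constraint was exercised rather than vacuous
    assert max(np.sqrt((br.w_depthwise.data ** 2).sum(axis=1)).max()
               for br in (model.branch_a, model.branch_b)) > 0.9


def test_save_load_round_trip(tiny_model_config, rng, tmp_path):
    model = build_model(tiny_model_config, seed=5)
    X = rng.normal(size=(3, 6, 64))
    path = tmp_path / "model.ckpt"
    model.save(path)
    from fcnna.model import FCNNAModel
    clone = FCNNAModel.load(path)
    assert np.allclose(model.predict_proba(X), clone.predict_proba(X))


def test_summary_mentions_every_layer(tiny_model_config):
    text = build_model(tiny_model_config, seed=0).summary()
    for token in ("temporal_conv", "depthwise_conv", "separable_conv",
                  "cbam", "concatenate", "dense", "total parameters"):
        assert token in text


def test_capacity_on_separable_data(rng):
    """On strongly separated synthetic trials the reduced model reaches high
    training accuracy within 50 epochs (capacity sanity)."""
    from fcnna.synthetic import SyntheticSpec, generate_dataset
    from fcnna.training import TrainConfig, train_model

    spec = SyntheticSpec(
        n_subjects=1, n_sessions=1, trials_per_session=200, n_channels=6,
        fs=80.0, trial_duration=1.6, cue_onset=0.2,
        imagination_duration=1.2, n_classes=4, erd_depth=0.9, ers_gain=0.0,
        snr=2.0, class_channel_map={1: {0, 1}, 2: {2, 3}, 3: {4}, 4: {5}},
        seed=21)
    ts = generate_dataset(spec)[(1, 1)]
    model = build_model(tiny_config(C=6, T=ts.n_samples, N=4), seed=0)
    cfg = TrainConfig(epochs=50, batch_size=8, repeats=1, seed=0,
                      monitor="validation", validation_fraction=0.1)
    model, _ = train_model(model, ts.data, ts.labels, cfg)
    train_acc = (model.predict(ts.data) == ts.labels).mean()
    assert train_acc >= 0.9, f"training accuracy only {train_acc:.2f}"
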