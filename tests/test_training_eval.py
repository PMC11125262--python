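"""Split bookkeeping, the metric suite against hand arithmetic and
scikit-learn cross-checks, and checkpointing behaviour."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support

from fcnna.errors import ConfigurationError
from fcnna.evaluation import (cohen_kappa, confusion_matrix,
                              per_class_metrics, report_from_predictions,
                              roc_auc_ovr)
from fcnna.synthetic import SyntheticSpec, generate_dataset
from fcnna.training import (TrainConfig, assemble, cross_subject_split,
                            one_hot, train_model, within_subject_split)


# Splits -------------------------------------------------------------

def test_within_subject_counts(small_dataset, small_spec):
    plan = within_subject_split(small_dataset, 1)
    assert len(plan.train_refs) == small_spec.trials_per_session
    assert len(plan.test_refs) == small_spec.trials_per_session
    assert {r[1] for r in plan.train_refs} == {1}
    assert {r[1] for r in plan.test_refs} == {2}
    assert not set(plan.train_refs) & set(plan.test_refs)


def test_emulated_reference_layout_counts():
    """On the 9-subject, 2x288-trial layout the splits give 288/288 within
    subject and 4608/576 cross subject."""
    dataset = {}
    for s in range(1, 10):
        for e in (1, 2):
            dataset[(s, e)] = type("TS", (), {"n_trials": 288})()
    w = within_subject_split(dataset, 3)
    assert (len(w.train_refs), len(w.test_refs)) == (288, 288)
    c = cross_subject_split(dataset, 3)
    assert (len(c.train_refs), len(c.test_refs)) == (4608, 576)


def test_cross_subject_partition(small_dataset):
    plan = cross_subject_split(small_dataset, 2)
    assert {r[0] for r in plan.test_refs} == {2}
    assert 2 not in {r[0] for r in plan.train_refs}
    total = {(s, e, i) for s, e in small_dataset
             for i in range(small_dataset[(s, e)].n_trials)}
    assert set(plan.train_refs) | set(plan.test_refs) == total
    assert not set(plan.train_refs) & set(plan.test_refs)


def test_split_errors(small_dataset):
    single = {(1, 1): small_dataset[(1, 1)]}
    with pytest.raises(ConfigurationError):
        within_subject_split(single, 1)
    with pytest.raises(ConfigurationError):
        cross_subject_split(small_dataset, 99)


def test_assemble_matches_refs(small_dataset):
    plan = within_subject_split(small_dataset, 1)
    X, y = assemble(plan.train_refs, small_dataset)
    ts = small_dataset[(1, 1)]
    assert np.array_equal(X, ts.data)
    assert np.array_equal(y, ts.labels)


# Metrics ------------------------------------------------------------

def test_confusion_matrix_counts():
    y_true = [1, 1, 2, 2, 2, 3]
    y_pred = [1, 2, 2, 2, 3, 3]
    cm = confusion_matrix(y_true, y_pred, 3)
    assert cm.tolist() == [[1, 1, 0], [0, 2, 1], [0, 0, 1]]
    assert cm.sum() == len(y_true)


def test_kappa_reference_values():
    # perfect agreement
    assert cohen_kappa(np.diag([10, 20, 30])) == pytest.approx(1.0)
    # uniform matrix: observed equals chance agreement
    assert cohen_kappa(np.full((4, 4), 5)) == pytest.approx(0.0)
    # hand computation: Po = 0.8, Pe = (40*40 + 60*60)/100^2 = 0.52
    cm = np.array([[30, 10], [10, 50]])
    assert cohen_kappa(cm) == pytest.approx((0.8 - 0.52) / (1 - 0.52))


def test_kappa_matches_sklearn(rng):
    y_true = rng.integers(1, 5, 300)
    y_pred = np.where(rng.random(300) < 0.6, y_true, rng.integers(1, 5, 300))
    cm = confusion_matrix(y_true, y_pred, 4)
    assert cohen_kappa(cm) == pytest.approx(
        cohen_kappa_score(y_true, y_pred), abs=1e-12)


def test_kappa_degenerate_matrix_rejected():
    with pytest.raises(ConfigurationError):
        cohen_kappa(np.array([[5, 0], [0, 0]]))  # Pe = 1
    with pytest.raises(ConfigurationError):
        cohen_kappa(np.zeros((2, 2)))


def test_per_class_counts_and_rates():
    # one flipped label from a perfect 2x50 split
    cm = np.array([[49, 1], [0, 50]])
    mets = per_class_metrics(cm)
    assert (mets[0].tp, mets[0].fn, mets[0].fp, mets[0].tn) == (49, 1, 0, 50)
    assert mets[0].precision == pytest.approx(1.0)
    assert mets[0].recall == pytest.approx(49 / 50)
    assert mets[1].precision == pytest.approx(50 / 51)
    acc = np.trace(cm) / cm.sum()
    assert acc == pytest.approx(0.99)


def test_metrics_match_sklearn(rng):
    y_true = rng.integers(1, 5, 400)
    y_pred = np.where(rng.random(400) < 0.5, y_true, rng.integers(1, 5, 400))
    cm = confusion_matrix(y_true, y_pred, 4)
    mets = per_class_metrics(cm)
    p, r, f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[1, 2, 3, 4], zero_division=0)
    for k in range(4):
        assert mets[k].precision == pytest.approx(p[k])
        assert mets[k].recall == pytest.approx(r[k])
        assert mets[k].f1 == pytest.approx(f[k])


def test_f1_harmonic_mean_identity(rng):
    y_true = rng.integers(1, 3, 200)
    y_pred = rng.integers(1, 3, 200)
    cm = confusion_matrix(y_true, y_pred, 2)
    for m in per_class_metrics(cm):
        if m.precision + m.recall > 0:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall))


def test_binary_macro_recall_equals_balanced_accuracy(rng):
    from sklearn.metrics import balanced_accuracy_score
    y_true = rng.integers(1, 3, 300)
    y_pred = rng.integers(1, 3, 300)
    cm = confusion_matrix(y_true, y_pred, 2)
    macro_recall = np.mean([m.recall for m in per_class_metrics(cm)])
    assert macro_recall == pytest.approx(
        balanced_accuracy_score(y_true, y_pred))


def test_kappa_bounded_by_accuracy(rng):
    for _ in range(20):
        y_true = rng.integers(1, 5, 100)
        y_pred = rng.integers(1, 5, 100)
        cm = confusion_matrix(y_true, y_pred, 4)
        acc = np.trace(cm) / cm.sum()
        assert cohen_kappa(cm) <= acc + 1e-12


def test_kappa_null_distribution(rng):
    """Label-independent predictions give kappa centred at zero."""
    kappas = []
    y_true = np.repeat([1, 2, 3, 4], 50)
    for _ in range(100):
        y_pred = rng.permutation(y_true)
        kappas.append(cohen_kappa(confusion_matrix(y_true, y_pred, 4)))
    assert abs(np.mean(kappas)) < 3 * np.std(kappas) / np.sqrt(len(kappas)) \
        + 0.01


def test_random_scorer_auc_near_half(rng):
    n = 1000
    y_true = rng.integers(1, 5, n)
    scores = rng.random((n, 4))
    scores /= scores.sum(axis=1, keepdims=True)
    _, macro = roc_auc_ovr(y_true, scores, 4)
    assert macro == pytest.approx(0.5, abs=0.05)


def test_perfect_predictions_report():
    y = np.repeat([1, 2, 3, 4], 10)
    scores = np.eye(4)[y - 1]
    rep = report_from_predictions(y, y, scores, 4)
    assert rep.accuracy == 1.0 and rep.kappa == pytest.approx(1.0)
    for m in rep.per_class:
        assert m.precision == m.recall == m.f1 == 1.0
    assert rep.macro_auc == pytest.approx(1.0)
    assert rep.confusion.sum() == len(y)


def test_empty_test_set_rejected():
    with pytest.raises(ConfigurationError):
        report_from_predictions([], [], None, 4)


def test_one_hot_encoding():
    enc = one_hot(np.array([1, 3, 2]), 3)
    assert enc.tolist() == [[1, 0, 0], [0, 0, 1], [0, 1, 0]]
    with pytest.raises(ConfigurationError):
        one_hot(np.array([0, 1]), 3)


# Training loop ------------------------------------------------------

def _quick_data(rng, n=40, C=4, T=64):
    X = rng.normal(size=(n, C, T)).astype(np.float32)
    y = rng.integers(1, 5, n)
    return X, y


def test_checkpoint_keeps_best_monitored_weights(rng):
    from fcnna.model import build_model, tiny_config
    X, y = _quick_data(rng)
    Xt, yt = _quick_data(rng, n=24)
    model = build_model(tiny_config(C=4, T=64, N=4), seed=0)
    cfg = TrainConfig(epochs=6, batch_size=8, repeats=1, monitor="test",
                      seed=0)
    model, hist = train_model(model, X, y, cfg, Xt, yt)
    best = max(hist["monitor_accuracy"])
    assert hist["monitor_accuracy"][hist["best_epoch"]] == best
    # restored weights reproduce the checkpointed accuracy
    assert (model.predict(Xt) == yt).mean() == pytest.approx(best)


def test_training_reproducible_with_seed(rng):
    from fcnna.model import build_model, tiny_config
    X, y = _quick_data(rng)
    histories = []
    for _ in range(2):
        model = build_model(tiny_config(C=4, T=64, N=4), seed=7)
        cfg = TrainConfig(epochs=3, batch_size=8, repeats=1, seed=11)
        _, hist = train_model(model, X, y, cfg)
        histories.append(hist["loss"])
    assert histories[0] == histories[1]


def test_null_data_stays_at_chance(rng):
    """Label-free data cannot be classified above chance bounds."""
    from fcnna.model import build_model, tiny_config
    spec = SyntheticSpec(
        n_subjects=1, n_sessions=2, trials_per_session=48, n_channels=4,
        fs=80.0, trial_duration=1.6, cue_onset=0.2,
        imagination_duration=1.2, n_classes=4, erd_depth=0.0, ers_gain=0.0,
        class_channel_map={1: {0}, 2: {1}, 3: {2}, 4: {3}}, seed=9)
    ds = generate_dataset(spec)
    model = build_model(tiny_config(C=4, T=ds[(1, 1)].n_samples, N=4), seed=0)
    cfg = TrainConfig(epochs=10, batch_size=16, repeats=1, monitor="test",
                      seed=0)
    model, hist = train_model(model, ds[(1, 1)].data, ds[(1, 1)].labels, cfg,
                              ds[(1, 2)].data, ds[(1, 2)].labels)
    n = spec.trials_per_session
    bound = 0.25 + 3 * np.sqrt(0.25 * 0.75 / n)
    assert max(hist["monitor_accuracy"]) <= bound + 0.05
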