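"""Desk-scale study recipes.

The reference study trains for 1000 epochs on 288-trial sessions at 250 Hz —
GPU-scale work.  These recipes reproduce each qualitative claim at single-CPU
scale: shorter trials at a lower sampling rate, fewer trials, reduced epochs,
and (for the electrode-selection study) the reduced-width model.  All
problem sizes are fixed here so tests and scripts exercise identical
conditions; every function takes one integer seed controlling all
randomness.
"""

from __future__ import annotations

import numpy as np

from .ga import GAConfig, make_model_fitness, run_ga
from .model import ModelConfig, tiny_config
from .preprocessing import (FilterSpec, WindowSpec, bandpass_filter,
                            window_trialset)
from .synthetic import SyntheticSpec, generate_dataset, informative_channels
from .training import TrainConfig, within_subject_split, run_split


def _sub_seed(seed: int, stream: int) -> int:
    ss = np.random.SeedSequence([int(seed), stream])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _preprocess(dataset, cue_onset, post_cue, high_hz):
    window = WindowSpec(pre_cue=0.5, post_cue=post_cue)
    filt = FilterSpec(low_hz=0.25, high_hz=high_hz, order=3)
    return {k: bandpass_filter(window_trialset(ts, cue_onset, window), filt)
            for k, ts in dataset.items()}


def strong_effect_training(seed: int, erd_depth: float = 0.9,
                           epochs: int = 50) -> dict:
    """Within-subject training sanity at desk scale.

    One subject, two 128-trial sessions over the 22-electrode montage at
    80 Hz (2.8 s trials, cue at 1 s), window 0.5 + 1.1 s -> T = 128,
    bandpass 0.25-35 Hz.  The full-width dual-branch model trains for
    ``epochs`` epochs (batch 16, Adam lr 9e-4) with the best-checkpoint
    callback monitoring the test session.  Strong, spatially coherent
    ERD/ERS (depth 0.9, snr 2) makes the four classes separable by
    construction, so test accuracy far above chance demonstrates that the
    model extracts the imposed band-power structure.
    """
    spec = SyntheticSpec(
        n_subjects=1, n_sessions=2, trials_per_session=128, n_channels=22,
        fs=80.0, trial_duration=2.8, cue_onset=1.0,
        imagination_duration=1.2, n_classes=4, erd_depth=erd_depth,
        ers_gain=0.5, snr=2.0, seed=_sub_seed(seed, 0))
    dataset = _preprocess(generate_dataset(spec), spec.cue_onset,
                          post_cue=1.1, high_hz=35.0)
    T = next(iter(dataset.values())).n_samples
    model_cfg = ModelConfig(C=22, T=T, N=4)
    train_cfg = TrainConfig(epochs=epochs, batch_size=16, repeats=1,
                            monitor="test", seed=_sub_seed(seed, 1))
    plan = within_subject_split(dataset, 1)
    _, report, history = run_split(dataset, plan, model_cfg, train_cfg,
                                   model_seed=_sub_seed(seed, 2))
    return {
        "test_accuracy": max(history["monitor_accuracy"]),
        "final_accuracy": report.accuracy,
        "kappa": report.kappa,
        "history": history,
        "n_train": len(plan.train_refs),
        "n_test": len(plan.test_refs),
    }


def null_effect_training(seed: int, epochs: int = 10) -> dict:
    """The same protocol on effect-free data (erd = ers = 0) with the
    reduced model: accuracy must stay within chance bounds."""
    spec = SyntheticSpec(
        n_subjects=1, n_sessions=2, trials_per_session=64, n_channels=22,
        fs=80.0, trial_duration=2.8, cue_onset=1.0,
        imagination_duration=1.2, n_classes=4, erd_depth=0.0, ers_gain=0.0,
        snr=2.0, seed=_sub_seed(seed, 10))
    dataset = _preprocess(generate_dataset(spec), spec.cue_onset,
                          post_cue=1.1, high_hz=35.0)
    T = next(iter(dataset.values())).n_samples
    model_cfg = tiny_config(C=22, T=T, N=4)
    train_cfg = TrainConfig(epochs=epochs, batch_size=16, repeats=1,
                            monitor="test", seed=_sub_seed(seed, 11))
    plan = within_subject_split(dataset, 1)
    _, report, history = run_split(dataset, plan, model_cfg, train_cfg,
                                   model_seed=_sub_seed(seed, 12))
    n = len(plan.test_refs)
    return {
        "best_accuracy": max(history["monitor_accuracy"]),
        "chance": 1.0 / 4,
        "chance_bound": 0.25 + 3 * float(np.sqrt(0.25 * 0.75 / n)),
        "n_test": n,
    }


RECOVERY_INFORMATIVE = frozenset({7, 8, 10, 11})  # C3, C1 vs C2, C4


def channel_recovery_run(seed: int) -> dict:
    """One electrode-selection run against known ground truth.

    Three subjects (two 32-trial sessions each) carry a two-class
    discrimination whose information lives in exactly four electrodes of the
    22-channel montage (left- vs right-hemisphere motor pairs).  The genetic
    algorithm — population 6, 3 generations, roulette selection, the
    two-segment crossover and 0.5-probability mutation — scores chromosomes
    by cross-subject test accuracy of the reduced-width model trained for 12
    epochs.  Returns the top chromosome's overlap with the informative set
    and the hypergeometric expectation for a random subset of the same size.
    """
    spec = SyntheticSpec(
        n_subjects=3, n_sessions=2, trials_per_session=32, n_channels=22,
        fs=80.0, trial_duration=2.8, cue_onset=1.0,
        imagination_duration=1.2, n_classes=2,
        class_channel_map={1: {7, 8}, 2: {10, 11}},
        erd_depth=0.9, ers_gain=0.5, snr=2.0, seed=_sub_seed(seed, 20))
    dataset = _preprocess(generate_dataset(spec), spec.cue_onset,
                          post_cue=1.1, high_hz=35.0)
    T = next(iter(dataset.values())).n_samples
    informative = informative_channels(spec)
    assert informative == set(RECOVERY_INFORMATIVE)

    ga_cfg = GAConfig(population_size=6, generations=3, runs=1,
                      fitness_epochs=12, init_length_range=(4, 12),
                      seed=_sub_seed(seed, 21))
    fit_train = TrainConfig(epochs=ga_cfg.fitness_epochs, batch_size=16,
                            repeats=1, monitor="test",
                            seed=_sub_seed(seed, 22))
    fitness = make_model_fitness(
        dataset, test_subject=1,
        model_config_fn=lambda n_ch: tiny_config(C=n_ch, T=T, N=2),
        train_cfg=fit_train)
    records = run_ga(fitness, list(range(22)), ga_cfg)
    top = records[0].chromosome
    overlap = len(set(top) & informative)
    expectation = len(top) * len(informative) / 22.0
    return {
        "top_channels": list(top.genes),
        "top_fitness": records[0].fitness,
        "overlap": overlap,
        "hypergeometric_expectation": expectation,
        "beats_null": overlap > expectation,
        "n_evaluations": len(records),
    }


def roulette_frequency_error(seed: int, n_draws: int = 100_000) -> float:
    """Max |empirical - theoretical| roulette frequency over 3 arms."""
    from .ga import Chromosome, roulette_select

    rng = np.random.default_rng(_sub_seed(seed, 30))
    pop = [Chromosome((i,)) for i in range(3)]
    fitnesses = [0.2, 0.3, 0.5]
    counts = np.zeros(3)
    for _ in range(n_draws):
        counts[roulette_select(pop, fitnesses, 1, rng)[0].genes[0]] += 1
    return float(np.abs(counts / n_draws - np.array(fitnesses)).max())
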