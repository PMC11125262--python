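# fcnna

EEG motor-imagery decoding with a dual-branch convolutional network,
convolutional block attention (CBAM), and genetic-algorithm electrode
selection.

Motor-imagery brain–computer interfaces classify which movement a subject
imagines (left hand, right hand, feet, tongue) from multichannel EEG.
Imagined movement suppresses mu (8–13 Hz) and beta (13–30 Hz) rhythm power
over contralateral sensorimotor cortex (ERD) and raises it nearby (ERS).
This package is a complete, tested pipeline for that problem, aimed at BCI
researchers who want a reproducible reference implementation that runs
end-to-end on synthetic data with known ground truth — no dataset download
required — and can also be pointed at real recordings.

## What's inside

- **`fcnna.synthetic`** — an MI-EEG generator emulating the standard
  9-subject × 2-session × 288-trial, 22-electrode, 250 Hz study layout:
  1/f background plus spatially coherent mu/beta rhythms with
  class-dependent ERD/ERS on known electrode subsets (the ground truth for
  everything downstream).
- **`fcnna.preprocessing`** — cue-locked windowing (0.5 s pre-cue + 4 s
  imagination = 1125 samples at 250 Hz) and zero-phase 3rd-order Butterworth
  bandpass (0.25–50 Hz); channel sub-setting; an optional GDF reader
  (`pip install fcnna[gdf]`).
- **`fcnna.model`** — the dual-branch classifier. Per branch: temporal
  convolution (F1 filters, width KE1) → depthwise spatial convolution over
  all electrodes (depth D, max-norm 1) → separable convolution (F2 = F1·D),
  with batch norm, ELU, average pooling and dropout; a CBAM block per
  branch; concatenation → dense softmax. Branch defaults F1=96, D=2, KE1=60
  and F1=16, D=1, KE1=64. Runs on a small numpy autodiff engine
  (`fcnna.nn`) — no deep-learning framework needed.
- **`fcnna.attention`** — CBAM: Mc = σ(MLP(avg) + MLP(max)) over filters,
  Ms = σ(conv₁ₓ₇[avg; max]) over time, applied multiplicatively in sequence.
- **`fcnna.training` / `fcnna.evaluation`** — within-subject (session 1 →
  session 2) and cross-subject (leave-one-subject-out) splits; Adam
  (lr 9e-4), cross-entropy, best-checkpoint training; confusion matrix,
  accuracy, Cohen's kappa, per-class precision/recall/F1, one-vs-rest
  ROC/AUC.
- **`fcnna.ga`** — electrode selection: chromosomes are channel subsets,
  fitness is cross-subject accuracy, with roulette selection, two-segment
  crossover, mutation and elitist replacement; converts ranked candidates
  into one **fixed** set shared by all subjects and **variable** per-subject
  sets.
- **`fcnna.pipeline` / `fcnna.cli`** — a YAML-driven pipeline with a run
  manifest, plus a thin `fcnna` command (`synth`, `preprocess`, `train`,
  `evaluate`, `select-channels`, `pipeline`).

See `docs/methods.md` for the model, the generator's assumptions, and all
numerical choices. The `examples/` scripts are short narrated walkthroughs
of each capability.

## Worked example

```python
from fcnna import (FilterSpec, SyntheticSpec, TrainConfig, WindowSpec,
                   bandpass_filter, generate_dataset, window_trialset,
                   within_subject_split)
from fcnna.model import ModelConfig
from fcnna.training import run_split

spec = SyntheticSpec(
    n_subjects=1, n_sessions=2, trials_per_session=128, n_channels=22,
    fs=80.0, trial_duration=2.8, cue_onset=1.0, imagination_duration=1.2,
    n_classes=4, erd_depth=0.9, ers_gain=0.5, snr=2.0, seed=11)
dataset = generate_dataset(spec)
dataset = {k: bandpass_filter(
               window_trialset(ts, spec.cue_onset, WindowSpec(0.5, 1.1)),
               FilterSpec(0.25, 35.0, 3))
           for k, ts in dataset.items()}

plan = within_subject_split(dataset, subject=1)          # 128 / 128 trials
model, report, history = run_split(
    dataset, plan, ModelConfig(C=22, T=128, N=4),
    TrainConfig(epochs=50, batch_size=16, repeats=1, monitor="test",
                seed=3))
print(round(max(history["monitor_accuracy"]), 3), round(report.kappa, 3))
```

This trains the full-width model for 50 epochs on one synthetic subject
(a few minutes on one CPU) and prints

```
0.984 0.979
```

— best test accuracy 98.4% against a 25% chance level, with a
chance-corrected kappa of 0.979: the network has recovered the imposed
ERD/ERS structure from raw microvolt traces. With `erd_depth=0.0,
ers_gain=0.0` the same protocol stays at chance (~25%), confirming there is
no information leak.

For electrode selection, `examples/04_ga_channel_selection.py` runs the GA
against a study whose information lives in exactly four electrodes and
prints the recovered set, its overlap with the ground truth, and the
fixed/variable deliverables.

## Using real recordings

`fcnna.preprocessing.load_gdf_session` reads a BCI Competition IV 2a GDF
session into a `TrialSet` (requires `mne`). Apply the same windowing,
filtering, and `run_split` calls as above with
`TrainConfig(epochs=1000, batch_size=64, repeats=10)` and
`ModelConfig(C=22, T=1125, N=4)` to mirror the reference protocol; be aware
the numpy engine makes this a long CPU run.
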