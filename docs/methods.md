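# Methods

## Problem setting

Motor-imagery (MI) brain–computer interfaces decode which movement a subject
imagines from multichannel EEG. Imagining a movement suppresses band-limited
power in the mu (8–13 Hz) and beta (13–30 Hz) rhythms over the contralateral
sensorimotor cortex (event-related desynchronization, ERD) and can raise it
over adjacent areas (event-related synchronization, ERS). This package
implements a complete decoding pipeline around that phenomenology: a
synthetic MI-EEG generator with known ground truth, the standard windowing
and bandpass preprocessing, a dual-branch convolutional classifier with
convolutional block attention (CBAM), within-/cross-subject evaluation with
the full metric suite, and a genetic algorithm (GA) that selects electrode
subsets by classification fitness.

## The classifier

Each of the two branches follows the EEGNet-style factorization:

1. **Temporal convolution** — F1 filters of shape 1×KE1 with "same" padding,
   acting per electrode. These learn frequency-selective kernels
   (KE1 = 60 and 64 samples in the two branches, roughly a quarter second
   at 250 Hz).
2. **Depthwise spatial convolution** — for each temporal filter, D kernels
   spanning all C electrodes ("valid" over the electrode axis), under a
   max-norm-1 constraint. These learn spatial patterns such as
   contralateral ERD topographies; the electrode axis collapses to 1.
3. **Separable convolution** — a depthwise 1×16 temporal kernel per feature
   map followed by a pointwise 1×1 convolution to F2 = F1·D maps.

Batch normalization, ELU, average pooling (1×4 after the depthwise stage,
1×8 after the separable stage) and dropout 0.5 follow each block. Branch A
defaults to F1=96, D=2, KE1=60; branch B to F1=16, D=1, KE1=64. For the
reference input (C=22, T=1125) each branch ends in a 1×35 map with 192 and
16 filters respectively; after CBAM the two maps are concatenated, flattened
(35 × 208 = 7280 values) and classified by a dense softmax layer.

**CBAM.** Channel attention gates each feature map:
Mc = σ(MLP(avgpool F) + MLP(maxpool F)), with a shared bottleneck MLP
(hidden width max(C_f/r, 1), r = 16 by default, ReLU on the hidden layer).
Spatial attention gates each temporal bin:
Ms = σ(conv₁ₓ₇([avgpool_c F′; maxpool_c F′])). The refined output is
F″ = Ms ⊗ (Mc ⊗ F). Because the electrode axis is already collapsed, the
spatial kernel is 1×7 rather than 7×7. The two pooling paths share MLP
weights (the original CBAM design); with all attention parameters at zero
both gates are exactly 0.5, so F″ = 0.25·F — a useful closed-form check.

**Numerical core.** No deep-learning framework is used; the model runs on a
small reverse-mode autodiff engine over numpy arrays (`fcnna.nn`), with
convolutions expressed as unfold + matrix multiplication and a fused
batch-norm primitive. Float32 is the working precision; float64 is
preserved when supplied, which the test suite uses for central-difference
gradient checks of every primitive and of the assembled model. Weights are
Glorot-uniform with a caller-supplied seed; biases start at zero.

## Training protocol

Adam (lr 9e-4, β₁ 0.9, β₂ 0.999, ε 1e-7), categorical cross-entropy,
batch size 64, 1000 epochs and 10 restarts are the reference defaults; a
best-checkpoint callback keeps the weights with the highest monitored
accuracy. The monitored set defaults to a held-out 10% validation fraction;
`monitor="test"` reproduces the protocol of monitoring the test split
directly (this leaks the test set into checkpoint selection, so the choice
is always explicit). One-hot labels are ordered 1..N. Divergence (non-finite
loss) raises with the epoch index. Batch-norm running statistics use
momentum 0.9 — with short desk-scale schedules a slower update (e.g. 0.99)
leaves inference-mode statistics far from the batch statistics.

Two split strategies: *within-subject* (session 1 trains, session 2 tests —
288/288 trials on the emulated layout) and *cross-subject* (both sessions of
one held-out subject test a model trained on all other subjects — 4608/576).

Metrics come from the confusion matrix (rows true, columns predicted):
accuracy; Cohen's kappa (Po − Pe)/(1 − Pe) with Pe from the marginal
products; one-vs-rest TP/TN/FP/FN per class with precision, recall and F1;
one-vs-rest ROC curves with trapezoidal AUC, macro-averaged. Kappa and the
per-class rates are computed directly from counts and cross-checked against
scikit-learn in the tests.

## Genetic-algorithm electrode selection

A chromosome is a duplicate-free sorted subset of the 22-electrode universe;
fitness is cross-subject test accuracy of the classifier trained on those
electrodes only. Per generation: roulette selection (pᵢ = fᵢ/Σfⱼ, three
distinct parents, sampled without replacement), two-segment crossover of the
two fitter parents, mutation of the third with probability 0.5 (replacing
k ~ U{1..⌈len/2⌉} genes with unused channels), and replacement of the three
least-fit members — population size stays 6, so the best chromosome always
survives and best fitness is monotone. Reference protocol: 3 generations ×
6 chromosomes, 300 fitness epochs, 3 independent runs; each distinct
chromosome is evaluated once per run (fitness cache), and an optional
fitness threshold stops a run early.

Crossover convention (the only one reproducing the published worked example
exactly): child₁ = parent₁[0..p₁] + parent₂[p₂..end], child₂ =
parent₂[0..p₃] + parent₁[p₄..end], segment ends inclusive, duplicates
dropped keeping the first occurrence, then sorted. Note a consequence: cut
pairs that leave a positional gap can drop genes, so even identical parents
need not reproduce themselves unless the segments cover all positions.
Initial chromosome lengths are drawn uniformly from (4, 16) by default
(published selected sets span 5–13 channels).

From the ranked records, the *fixed* deliverable is the single candidate
with the best mean within-subject accuracy across subjects (ties broken
toward fewer electrodes); the *variable* deliverable assigns each subject
its own best candidate, which by construction can never score below the
fixed set for that subject.

Channel indices are 0-based internally and 1-based in all user-facing I/O,
matching the conventional 1..22 numbering of the montage
(Fz, FC3…FC4, C5…C6, CP3…CP4, P1, Pz, P2, POz).

## Synthetic data generator

Each trial is 1/f-shaped Gaussian background noise (exponent 1, RMS 10 µV
per channel) plus ongoing mu and beta rhythms on every channel (mu amplitude
= snr × background RMS, beta 0.6× that). During the imagination interval
(cue at 2 s, 4 s duration by default, raised-cosine ramps of 0.2 s) the
rhythm amplitude is multiplied by (1 − erd_depth) on the imagined class's
informative channels and by (1 + ers_gain) on the paired class's channels.
The default montage map places left-hand information on the right motor
strip (C2, C4, CP2, CP4), right-hand on the left strip (C3, C1, CP3, CP1),
feet on the midline (FCz, Cz, CPz) and tongue laterally (C5, C6).

The informative channels of one class share a single latent rhythm source
(with independent rhythms on the remaining channels). This mirrors volume
conduction: a cortical rhythm generator projects coherently to neighbouring
electrodes, which is precisely the structure spatial filters exploit. With
fully independent per-channel rhythms the class signal would live only in
per-channel variances, which a linear spatial stage cannot pool coherently —
a band-power periodogram oracle still separates such classes, but no
spatial-filter architecture can learn them efficiently at small trial
counts, so coherent sources are both the more realistic and the more
informative emulation.

Inter-subject variability is multiplicative jitter (±15%) on erd_depth and
snr, drawn per subject from the dataset seed, which makes cross-subject
generalization measurably harder than within-subject — the qualitative
ordering seen in real MI studies. All randomness flows through
`numpy.random.SeedSequence` spawning, so a spec (including its seed)
determines the dataset bit-for-bit.

What the generator does *not* emulate: ocular/muscle artifacts,
non-stationarity within a session, electrode drift, dipolar forward-model
topographies beyond the shared-source approximation, and any calibration of
effect sizes to the real recordings (the reference study never states its
ERD depth). Passing tests therefore demonstrate that the pipeline recovers
structure it is designed for, not that it attains any particular accuracy
on real data.

## Desk-scale study sizes

The reference protocol (1000 epochs, 288-trial sessions at 250 Hz,
10 restarts) is GPU-scale. The package's own experiments
(`fcnna.experiments`) shrink the conditions, chosen once as follows:

- **Training sanity** — 1 subject × 2 × 128 trials, 22 channels, 80 Hz,
  2.8 s trials (cue 1 s, imagination 1.2 s), window 0.5 + 1.1 s → T = 128,
  bandpass 0.25–35 Hz, erd 0.9 / ers 0.5 / snr 2, full-width model,
  50 epochs, batch 16 (so ~400 gradient steps), test-monitored checkpoint.
  Typical best test accuracy ≈ 0.94 against a 0.25 chance level; the same
  protocol on effect-free data stays within binomial chance bounds.
- **Electrode recovery** — 3 subjects × 2 × 32 trials, two classes carried
  by exactly 4 of 22 electrodes ({C3, C1} vs {C2, C4}), reduced-width model
  (F1 = 8/4), 12 fitness epochs, GA with population 6 and 3 generations.
  The top chromosome's overlap with the informative set is compared with
  the hypergeometric expectation for its size; 5 seeded repetitions beat
  the null in 5/5 during development.
- **Statistical oracles** — roulette frequencies vs Eq.-level weights at
  10⁵ draws (±0.01), CBAM vectorized-vs-scalar-loop agreement on 100 random
  maps (<1e-6), metric identities on fixed confusion matrices.

## Numerical choices and edge cases

- Zero-phase (forward–backward) filtering via second-order sections; the
  effective magnitude response is the squared single-pass Butterworth
  response. The 0.25 Hz edge implies a multi-second impulse response, so
  amplitude checks must discard generous margins.
- Windows are 0-based and half-open; sample counts round (pre+post)×fs, so
  4.5 s × 250 Hz is exactly 1125. Average pooling floors its output width.
- "Same" padding splits asymmetrically for even kernels (left gets
  ⌊(k−1)/2⌋).
- Attention max-pool backward splits gradient equally among ties.
- Empty channel subsets, out-of-range cuts, degenerate single-cell
  confusion matrices (Pe = 1) and windows beyond trial bounds all raise
  typed errors rather than propagating nonsense.
- All-zero fitness vectors fall back to uniform roulette weights (logged).

## Known limitations

- The numpy engine is single-threaded and memory-bandwidth-bound; the
  full-width model at the reference input size (T=1125) trains at minutes
  per epoch on one CPU, so reproducing the 1000-epoch protocol on the real
  recordings needs the patience of a long run (or a GPU port).
- Fitness at 12 desk-scale epochs is a noisy estimate of a subset's worth;
  the GA tolerates this (selection is rank-robust) but individual fitness
  values should not be over-interpreted.
- ROC/AUC for a class absent from the test set is reported as NaN and
  excluded from the macro average.
- The optional GDF reader requires `mne` and the real recordings; it is a
  convenience path, not a tested surface.
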