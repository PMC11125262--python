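"""Window and filter trials, then walk through the classifier architecture.

Shows the standard preprocessing (0.5 s pre-cue + 4 s imagination window,
0.25-50 Hz 3rd-order zero-phase Butterworth) and prints the dual-branch
model's layer shapes for the reference 22-channel, 1125-sample input —
including the 192-filter, 35-bin feature map each attention block receives
and the 7280-long fused feature vector.
"""

from fcnna import (FilterSpec, ModelConfig, SyntheticSpec, WindowSpec,
                   bandpass_filter, generate_dataset, output_shapes,
                   window_trialset)

spec = SyntheticSpec(n_subjects=1, n_sessions=1, trials_per_session=8,
                     seed=3)  # defaults: 22 ch, 250 Hz, 7.5 s trials
ts = generate_dataset(spec)[(1, 1)]
print(f"raw trials: {ts.data.shape}")

window = WindowSpec(pre_cue=0.5, post_cue=4.0)
ts = window_trialset(ts, cue_onset=spec.cue_onset, window=window)
print(f"windowed to {ts.n_samples} samples "
      f"({window.pre_cue + window.post_cue} s at {ts.fs:.0f} Hz)")

ts = bandpass_filter(ts, FilterSpec(low_hz=0.25, high_hz=50.0, order=3))
print("bandpass 0.25-50 Hz applied (zero-phase, squared magnitude response)")

cfg = ModelConfig(C=ts.n_channels, T=ts.n_samples, N=4)
print("\nlayer walk (name, output shape):")
for name, shape in output_shapes(cfg):
    print(f"  {name:28s} {shape}")
print(f"\nfused feature vector: {cfg.flat_features()} values "
      f"= width {cfg.fused_width()} x "
      f"({cfg.branch_a.F2} + {cfg.branch_b.F2}) filters")
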