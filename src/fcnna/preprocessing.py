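"""Trial windowing, zero-phase Butterworth bandpass filtering and channel
sub-setting.

The analysis window covers the 4 s imagination period plus 0.5 s before cue
onset by default (4.5 s, i.e. 1125 samples at 250 Hz), and the default
bandpass keeps 0.25-50 Hz with a 3rd-order Butterworth design.  Filtering is
applied forward-backward (zero phase), so the effective magnitude response is
the squared single-pass response; no re-referencing, artifact rejection or
normalization is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigurationError, WindowRangeError
from .synthetic import TrialSet


@dataclass
class WindowSpec:
    """Analysis window around cue onset."""

    pre_cue: float = 0.5
    post_cue: float = 4.0

    def __post_init__(self):
        if self.pre_cue < 0:
            raise ConfigurationError("pre_cue must be >= 0")
        if self.post_cue <= 0:
            raise ConfigurationError("post_cue must be > 0")

    def n_samples(self, fs: float) -> int:
        return int(round((self.pre_cue + self.post_cue) * fs))


@dataclass
class FilterSpec:
    """Butterworth bandpass description."""

    low_hz: float = 0.25
    high_hz: float = 50.0
    order: int = 3
    design: str = "butterworth-bandpass"

    def __post_init__(self):
        if self.low_hz <= 0 or self.high_hz <= self.low_hz:
            raise ConfigurationError(
                f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})")
        if self.order < 1:
            raise ConfigurationError("order must be >= 1")
        if self.design != "butterworth-bandpass":
            raise ConfigurationError(f"unknown filter design {self.design!r}")

    def sos(self, fs: float):
        if self.high_hz >= fs / 2:
            raise ConfigurationError(
                f"high_hz ({self.high_hz}) must be below the Nyquist "
                f"frequency ({fs / 2})")
        return signal.butter(self.order, [self.low_hz, self.high_hz],
                             btype="bandpass", fs=fs, output="sos")


def extract_window(trial: np.ndarray, cue_onset: float, window: WindowSpec,
                   fs: float) -> np.ndarray:
    """Slice ``[cue_onset - pre_cue, cue_onset + post_cue)`` from one trial.

    ``trial`` is channels x samples; the result has exactly
    ``round((pre_cue + post_cue) * fs)`` samples per channel, starting at
    sample ``floor((cue_onset - pre_cue) * fs)`` (0-based, half-open).
    """
    trial = np.asarray(trial)
    start = int(np.floor((cue_onset - window.pre_cue) * fs))
    n = window.n_samples(fs)
    if start < 0 or start + n > trial.shape[-1]:
        raise WindowRangeError(
            f"window [{cue_onset - window.pre_cue:.3f}, "
            f"{cue_onset + window.post_cue:.3f}) s (samples "
            f"[{start}, {start + n})) exceeds trial of "
            f"{trial.shape[-1]} samples")
    return trial[..., start:start + n]


def window_trialset(trials: TrialSet, cue_onset: float,
                    window: WindowSpec) -> TrialSet:
    """Apply :func:`extract_window` to every trial of a set."""
    data = extract_window(trials.data, cue_onset, window, trials.fs)
    return trials.replace(data=data)


def bandpass_filter(trials: TrialSet, filt: FilterSpec) -> TrialSet:
    """Zero-phase (forward-backward) bandpass of every channel of every trial."""
    sos = filt.sos(trials.fs)
    data = signal.sosfiltfilt(sos, trials.data, axis=-1)
    return trials.replace(data=np.ascontiguousarray(data))


def select_channels(trials: TrialSet, subset) -> TrialSet:
    """Restrict a trial set to the (0-based) channel indices of ``subset``.

    ``subset`` may be a :class:`~fcnna.ga.Chromosome` or any iterable of
    indices; the original relative channel order is preserved.
    """
    genes = list(getattr(subset, "genes", subset))
    if len(genes) == 0:
        raise ConfigurationError("empty channel subset is not allowed")
    if len(set(genes)) != len(genes):
        raise ConfigurationError(f"duplicate channel indices in {genes}")
    for g in genes:
        if not 0 <= g < trials.n_channels:
            raise ConfigurationError(
                f"channel index {g} out of range for "
                f"{trials.n_channels}-channel data")
    order = sorted(genes)
    return trials.replace(
        data=trials.data[:, order, :],
        channel_names=[trials.channel_names[i] for i in order])


def load_gdf_session(path, montage_channels=22):
    """Optional reader for a BCI Competition IV 2a GDF session.

    Requires :mod:`mne` (``pip install fcnna[gdf]``).  Returns a
    :class:`TrialSet` of full-length trials whose cue onsets sit at the
    recording's standard 2 s offset, ready for :func:`window_trialset`.
    Never used by the test suite; provided as a convenience for running the
    pipeline on the real recordings.
    """
    import mne  # local import: optional dependency

    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    picks = mne.pick_types(raw.info, eeg=True)[:montage_channels]
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    # cue annotations 769..772 map to classes 1..4
    cue_ids = {k: int(k[-3:]) - 768 for k in event_id if k in
               ("769", "770", "771", "772")}
    if not cue_ids:
        raise ConfigurationError(f"no motor-imagery cues found in {path}")
    fs = raw.info["sfreq"]
    sig = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
    trial_len = int(round(7.5 * fs))
    pre_cue = int(round(2.0 * fs))
    data, labels = [], []
    for sample, _, code in events:
        name = {v: k for k, v in event_id.items()}.get(code)
        if name not in cue_ids:
            continue
        start = sample - pre_cue
        if start < 0 or start + trial_len > sig.shape[1]:
            continue
        data.append(sig[:, start:start + trial_len])
        labels.append(cue_ids[name])
    names = [raw.ch_names[i] for i in picks]
    return TrialSet(data=np.stack(data), labels=np.array(labels), fs=fs,
                    channel_names=names)
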