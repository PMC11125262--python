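"""Synthetic motor-imagery EEG with known ground truth.

The generator emulates the statistical structure a sensorimotor-rhythm
classifier relies on: every channel carries 1/f-shaped background activity
plus ongoing mu (8-13 Hz) and beta (13-30 Hz) rhythms; during the imagination
interval the rhythm amplitude drops by ``erd_depth`` on the channels
informative for the imagined class (event-related desynchronization) and
rises by ``ers_gain`` on a paired channel set (event-related
synchronization).  The default layout mirrors the BCI Competition IV 2a
recordings: 9 subjects x 2 sessions x 288 balanced trials over the
22-electrode 10-20 montage at 250 Hz, with cue onset at 2 s and a 4 s
imagination period inside a 7.5 s trial.

Because the informative channels are chosen by construction, the generator
doubles as ground truth for electrode-selection experiments: a channel
selector should recover (a superset of) the union of the per-class channel
sets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .montage import MONTAGE_22

Dataset = dict  # {(subject, session): TrialSet}

#: physiologically motivated channel sets on the 22-electrode montage
#: (0-based indices): left hand -> right motor strip, right hand -> left
#: motor strip, feet -> midline, tongue -> lateral central electrodes.
_DEFAULT_MAP_22 = {
    1: frozenset({10, 11, 16, 17}),   # C2, C4, CP2, CP4
    2: frozenset({7, 8, 13, 14}),     # C3, C1, CP3, CP1
    3: frozenset({3, 9, 15}),         # FCz, Cz, CPz
    4: frozenset({6, 12}),            # C5, C6
}


def default_class_channel_map(n_classes: int, n_channels: int) -> dict:
    """Informative-channel assignment used when the spec does not give one."""
    if n_channels == 22 and n_classes <= 4:
        return {k: set(_DEFAULT_MAP_22[k]) for k in range(1, n_classes + 1)}
    # generic fallback: consecutive disjoint pairs
    if 2 * n_classes > n_channels:
        raise ConfigurationError(
            f"cannot place {n_classes} disjoint channel pairs in "
            f"{n_channels} channels")
    return {k: {2 * (k - 1), 2 * (k - 1) + 1} for k in range(1, n_classes + 1)}


@dataclass
class SyntheticSpec:
    """Study-condition description for the synthetic generator."""

    n_subjects: int = 9
    n_sessions: int = 2
    trials_per_session: int = 288
    n_channels: int = 22
    fs: float = 250.0
    trial_duration: float = 7.5
    cue_onset: float = 2.0
    imagination_duration: float = 4.0
    n_classes: int = 4
    class_channel_map: dict | None = None
    class_ers_map: dict | None = None
    erd_depth: float = 0.6
    ers_gain: float = 0.3
    mu_band: tuple = (8.0, 13.0)
    beta_band: tuple = (13.0, 30.0)
    noise_exponent: float = 1.0
    snr: float = 1.0
    background_rms_uv: float = 10.0
    subject_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.class_channel_map is None:
            self.class_channel_map = default_class_channel_map(
                self.n_classes, self.n_channels)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 1:
            raise ConfigurationError("n_subjects and n_sessions must be >= 1")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.trials_per_session % self.n_classes != 0:
            raise ConfigurationError(
                f"trials_per_session ({self.trials_per_session}) must be "
                f"divisible by n_classes ({self.n_classes}) for balanced "
                "classes")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ConfigurationError(
                f"erd_depth must lie in [0, 1], got {self.erd_depth}")
        if self.ers_gain < 0:
            raise ConfigurationError("ers_gain must be >= 0")
        if self.fs <= 2 * self.beta_band[1]:
            raise ConfigurationError(
                f"fs ({self.fs}) must exceed twice the upper beta edge "
                f"({self.beta_band[1]})")
        for cls, chans in self.class_channel_map.items():
            if not 1 <= cls <= self.n_classes:
                raise ConfigurationError(
                    f"class_channel_map key {cls} outside 1..{self.n_classes}")
            for c in chans:
                if not 0 <= c < self.n_channels:
                    raise ConfigurationError(
                        f"informative channel index {c} for class {cls} is "
                        f"not < n_channels ({self.n_channels})")
        if self.cue_onset < 0 or self.imagination_duration <= 0:
            raise ConfigurationError("cue timing must be non-negative")
        if self.cue_onset + self.imagination_duration > self.trial_duration:
            raise ConfigurationError(
                "cue_onset + imagination_duration exceeds trial_duration")
        if self.snr < 0:
            raise ConfigurationError("snr must be >= 0")

    @property
    def channel_names(self):
        if self.n_channels == 22:
            return list(MONTAGE_22)
        return [f"ch{i + 1}" for i in range(self.n_channels)]

    def ers_channels(self, class_id: int) -> set:
        """ERS set for a class: explicit map, else the paired class's set."""
        if self.class_ers_map is not None:
            return set(self.class_ers_map.get(class_id, set()))
        partner = class_id + 1 if class_id % 2 == 1 else class_id - 1
        if partner in self.class_channel_map:
            paired = set(self.class_channel_map[partner])
            return paired - set(self.class_channel_map[class_id])
        return set()


@dataclass
class TrialSet:
    """Labelled multichannel EEG trials plus recording metadata."""

    data: np.ndarray            # (trials, channels, samples), microvolts
    labels: np.ndarray          # (trials,), values in 1..N
    fs: float
    channel_names: list
    subject_id: int | str = 0
    session_id: int | str = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ConfigurationError("data must be trials x channels x samples")
        if self.data.shape[0] != len(self.labels):
            raise ConfigurationError(
                f"data has {self.data.shape[0]} trials but "
                f"{len(self.labels)} labels")
        if self.data.shape[1] != len(self.channel_names):
            raise ConfigurationError(
                f"data has {self.data.shape[1]} channels but "
                f"{len(self.channel_names)} channel names")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if len(self.labels) and self.labels.min() < 1:
            raise ConfigurationError("labels must be >= 1")

    @property
    def n_trials(self):
        return self.data.shape[0]

    @property
    def n_channels(self):
        return self.data.shape[1]

    @property
    def n_samples(self):
        return self.data.shape[2]

    @property
    def n_classes(self):
        return int(self.labels.max()) if len(self.labels) else 0

    def replace(self, **kwargs) -> "TrialSet":
        return dataclasses.replace(self, **kwargs)


# Signal building blocks --------------------------------------------

def _colored_noise(rng, shape, exponent, fs):
    """Gaussian noise with a 1/f**exponent power spectrum, unit RMS per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    rms = np.sqrt((x * x).mean(axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _bandlimited_noise(rng, shape, band, fs):
    """Gaussian noise restricted to ``band`` Hz, unit RMS per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        raise ConfigurationError(f"band {band} is empty at fs={fs}")
    x = np.fft.irfft(spec * mask, n=n, axis=-1)
    rms = np.sqrt((x * x).mean(axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _modulation_envelope(spec: SyntheticSpec, n_samples: int, channels,
                         factor: float, ramp_s: float = 0.2) -> np.ndarray:
    """Per-channel amplitude envelope: ``factor`` inside the imagination
    window on ``channels``, 1 elsewhere, with raised-cosine ramps."""
    env = np.ones((spec.n_channels, n_samples))
    if not channels:
        return env
    t = np.arange(n_samples) / spec.fs
    start, stop = spec.cue_onset, spec.cue_onset + spec.imagination_duration
    ramp = min(ramp_s, spec.imagination_duration / 4.0)
    profile = np.zeros(n_samples)
    inside = (t >= start + ramp) & (t <= stop - ramp)
    profile[inside] = 1.0
    up = (t >= start) & (t < start + ramp)
    profile[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp))
    down = (t > stop - ramp) & (t <= stop)
    profile[down] = 0.5 * (1 - np.cos(np.pi * (stop - t[down]) / ramp))
    mod = 1.0 + (factor - 1.0) * profile
    env[sorted(channels), :] = mod
    return env


def _rhythm_field(spec: SyntheticSpec, n: int, amp_mu: float,
                  amp_beta: float, rng) -> np.ndarray:
    """Ongoing mu+beta rhythms on every channel.

    Channels belonging to one class's informative set share a single latent
    rhythm source — sensorimotor rhythms are spatially coherent over a
    cortical patch (volume conduction), which is what spatial filters
    exploit.  Remaining channels carry independent rhythms.
    """
    rhythm = np.zeros((spec.n_channels, n))
    assigned: set = set()
    for cls in sorted(spec.class_channel_map):
        chans = sorted(set(spec.class_channel_map[cls]) - assigned)
        if not chans:
            continue
        src = (amp_mu * _bandlimited_noise(rng, (1, n), spec.mu_band, spec.fs)
               + amp_beta * _bandlimited_noise(rng, (1, n), spec.beta_band,
                                               spec.fs))[0]
        rhythm[chans, :] = src
        assigned |= set(chans)
    rest = sorted(set(range(spec.n_channels)) - assigned)
    if rest:
        rhythm[rest, :] = (
            amp_mu * _bandlimited_noise(rng, (len(rest), n), spec.mu_band,
                                        spec.fs)
            + amp_beta * _bandlimited_noise(rng, (len(rest), n),
                                            spec.beta_band, spec.fs))
    return rhythm


def generate_trial(class_id: int, spec: SyntheticSpec,
                   rng: np.random.Generator,
                   erd_depth: float | None = None,
                   snr: float | None = None) -> np.ndarray:
    """One synthetic trial (channels x samples, microvolts)."""
    if class_id not in range(1, spec.n_classes + 1):
        raise ConfigurationError(
            f"unknown class {class_id}; expected 1..{spec.n_classes}")
    erd = spec.erd_depth if erd_depth is None else erd_depth
    s = spec.snr if snr is None else snr
    n = int(round(spec.trial_duration * spec.fs))
    C = spec.n_channels

    bg = _colored_noise(rng, (C, n), spec.noise_exponent, spec.fs)
    bg *= spec.background_rms_uv

    amp_mu = s * spec.background_rms_uv
    amp_beta = 0.6 * s * spec.background_rms_uv
    rhythm = _rhythm_field(spec, n, amp_mu, amp_beta, rng)

    erd_chans = set(spec.class_channel_map[class_id])
    ers_chans = spec.ers_channels(class_id) - erd_chans
    env = _modulation_envelope(spec, n, erd_chans, 1.0 - erd)
    env *= _modulation_envelope(spec, n, ers_chans, 1.0 + spec.ers_gain)

    return bg + rhythm * env


def _balanced_labels(spec: SyntheticSpec, rng) -> np.ndarray:
    per = spec.trials_per_session // spec.n_classes
    labels = np.repeat(np.arange(1, spec.n_classes + 1), per)
    rng.shuffle(labels)
    return labels


def generate_dataset(spec: SyntheticSpec) -> Dataset:
    """All (subject, session) trial sets of the emulated study.

    Per-subject multiplicative jitter on ``erd_depth`` and ``snr`` emulates
    inter-subject variability, so cross-subject generalization is harder than
    within-subject, as in real motor-imagery data.  Deterministic in
    ``spec.seed``.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    dataset: Dataset = {}
    for s_idx, subj_ss in enumerate(subject_seeds, start=1):
        jit_rng = np.random.default_rng(subj_ss)
        lo, hi = 1.0 - spec.subject_jitter, 1.0 + spec.subject_jitter
        erd_s = float(np.clip(spec.erd_depth * jit_rng.uniform(lo, hi), 0, 1))
        snr_s = float(spec.snr * jit_rng.uniform(lo, hi))
        session_seeds = subj_ss.spawn(spec.n_sessions)
        for e_idx, sess_ss in enumerate(session_seeds, start=1):
            rng = np.random.default_rng(sess_ss)
            labels = _balanced_labels(spec, rng)
            trials = np.stack([
                generate_trial(int(lab), spec, rng, erd_depth=erd_s, snr=snr_s)
                for lab in labels
            ])
            dataset[(s_idx, e_idx)] = TrialSet(
                data=trials, labels=labels, fs=spec.fs,
                channel_names=spec.channel_names,
                subject_id=s_idx, session_id=e_idx)
    return dataset


def informative_channels(spec: SyntheticSpec) -> set:
    """Union of all per-class informative channel indices (ground truth)."""
    out: set = set()
    for chans in spec.class_channel_map.values():
        out |= set(chans)
    return out


# Archive I/O -------------------------------------------------------

def save_dataset(dataset: Dataset, out_dir) -> None:
    """One compressed archive per (subject, session) plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = []
    for (subj, sess), ts in sorted(dataset.items()):
        name = f"subject{subj:02d}_session{sess:02d}.npz"
        np.savez_compressed(
            out / name, data=ts.data, labels=ts.labels, fs=ts.fs,
            channel_names=np.array(ts.channel_names))
        index.append({"subject": subj, "session": sess, "file": name})
    (out / "dataset.json").write_text(json.dumps({"sets": index}, indent=2))


def load_dataset(in_dir) -> Dataset:
    src = Path(in_dir)
    meta = json.loads((src / "dataset.json").read_text())
    dataset: Dataset = {}
    for entry in meta["sets"]:
        with np.load(src / entry["file"]) as z:
            dataset[(entry["subject"], entry["session"])] = TrialSet(
                data=z["data"], labels=z["labels"], fs=float(z["fs"]),
                channel_names=[str(c) for c in z["channel_names"]],
                subject_id=entry["subject"], session_id=entry["session"])
    return dataset
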