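import numpy as np
import pytest

from fcnna.attention import CBAMConfig
from fcnna.model import ConvBranchConfig, ModelConfig
from fcnna.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_spec():
    """A compact 2-subject layout for fast structural tests."""
    return SyntheticSpec(
        n_subjects=2, n_sessions=2, trials_per_session=8, n_channels=6,
        fs=80.0, trial_duration=2.0, cue_onset=0.5,
        imagination_duration=1.0, n_classes=4,
        class_channel_map={1: {0, 1}, 2: {2, 3}, 3: {4}, 4: {5}},
        seed=123)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def tiny_model_config():
    """A double-pooling dual-branch config small enough for direct forward
    checks."""
    return ModelConfig(
        C=6, T=64, N=4,
        branch_a=ConvBranchConfig(F1=4, D=2, KE1=9, KE2=5),
        branch_b=ConvBranchConfig(F1=2, D=1, KE1=11, KE2=5),
        cbam=CBAMConfig(reduction_ratio=2, spatial_kernel=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240516)
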