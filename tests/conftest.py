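import numpy as np
import pytest

from tapcrnn.synth import SynthConfig, synthesize_clip, synthesize_cohort


@pytest.fixture(scope="session")
def quick_config() -> SynthConfig:
    """Short, low-rate clips for fast unit tests."""
    return SynthConfig(rate=2000, duration=4.0, murmur_snr_db=10, seed=11)


@pytest.fixture(scope="session")
def murmur_clip(quick_config):
    return synthesize_clip(quick_config, "murmur")


@pytest.fixture(scope="session")
def normal_clip(quick_config):
    return synthesize_clip(quick_config, "normal")


@pytest.fixture(scope="session")
def tiny_cohort(quick_config):
    """3 murmur + 3 normal subjects, one clip per site (30 clips)."""
    return synthesize_cohort(3, 3, 1, quick_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
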