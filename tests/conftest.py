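from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from seizmon import FilterChainConfig, SyntheticSpec, generate_dataset

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def chain_cfg() -> FilterChainConfig:
    """Default chain: 6.8 Hz HP, 9-14 Hz band, 1 Hz smoothing at 625 Hz."""
    return FilterChainConfig()


@pytest.fixture(scope="session")
def high_snr_dataset():
    """600 s synthetic dataset, 10 events, strong 9-14 Hz bump (gain 30)."""
    spec = SyntheticSpec(duration_s=600.0, bump_gain=30.0, seed=0)
    rec, truth = generate_dataset(spec)
    return spec, rec, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_sine(freq_hz: float, amplitude_uv: float, duration_s: float, fs: float = 625.0):
    from seizmon import Recording

    t = np.arange(int(duration_s * fs)) / fs
    return Recording(amplitude_uv * np.sin(2 * np.pi * freq_hz * t), fs)
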