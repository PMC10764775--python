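import numpy as np
import pytest

from bitekin import BiteSimConfig, analyze_bite, simulate_bite


@pytest.fixture(scope="session")
def clean_bite():
    """Noise-free default simulated bite with its ground truth."""
    return simulate_bite(BiteSimConfig(noise_sd_mm=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_bite():
    """Default simulated bite with 0.05 mm landmark noise."""
    return simulate_bite(BiteSimConfig(noise_sd_mm=0.05, seed=1))


@pytest.fixture(scope="session")
def analyzed_clean(clean_bite):
    lset, truth = clean_bite
    profile, cycles, seg, summary = analyze_bite(lset)
    return lset, truth, profile, cycles, seg, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
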