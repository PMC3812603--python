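import numpy as np
import pytest

from eegattn.features import extract_dataset
from eegattn.io import ATTENTIVE, INATTENTIVE
from eegattn.preprocess import Segment
from eegattn.simulate import DEFAULT_BAND_TABLE, SyntheticConfig, generate_dataset


def brute_force_psd(x: np.ndarray) -> np.ndarray:
    """Independent O(N²) DFT periodogram: P(n) = |Σ_t x_t e^{-2πi nt/N}|²/N.

    Built from the explicit DFT matrix, deliberately avoiding any FFT
    routine, so it can serve as an oracle for the fast implementation.
    """
    N = x.size
    n = np.arange(N)
    W = np.exp(-2j * np.pi * np.outer(n, n) / N)
    F = W @ x
    return (F * F.conj()).real / N


def tone_segment(freq_hz: float, amplitude: float = 1.0, fs: float = 512.0, n: int = 512,
                 label: str = ATTENTIVE) -> Segment:
    """A pure sinusoid landing exactly on one DFT bin when freq is integer."""
    t = np.arange(n) / fs
    return Segment(samples=amplitude * np.sin(2 * np.pi * freq_hz * t), start_index=0, label=label)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_effect_dataset():
    """Six synthetic subjects, 12 s per state, default directional gains."""
    cfg = SyntheticConfig(seed=11)
    return extract_dataset(generate_dataset(6, 12, cfg))


@pytest.fixture(scope="session")
def separable_clouds():
    """Two well-separated 5-D Gaussian clouds, 50 points per class."""
    gen = np.random.default_rng(42)
    X = np.vstack(
        [
            gen.normal(loc=5.0, scale=1.0, size=(50, 5)),
            gen.normal(loc=-5.0, scale=1.0, size=(50, 5)),
        ]
    )
    y = np.array([ATTENTIVE] * 50 + [INATTENTIVE] * 50)
    return X, y


def beta_only_config(seed: int = 7) -> SyntheticConfig:
    """Generator whose only attentive/inattentive difference is beta power."""
    gains = {
        ATTENTIVE: {b: 1.0 for b in DEFAULT_BAND_TABLE},
        INATTENTIVE: {b: 1.0 for b in DEFAULT_BAND_TABLE},
    }
    gains[ATTENTIVE]["beta"] = 1.5
    return SyntheticConfig(seed=seed, state_gain=gains)
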