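import numpy as np
import pytest

from pacsoz import SurrogateSpec, SynthConfig, build_band_grid


@pytest.fixture(scope="session")
def grid():
    return build_band_grid()


@pytest.fixture(scope="session")
def small_cfg():
    """A short, cheap recording configuration used across unit tests."""
    return SynthConfig(
        fs=2000.0, duration=60.0, n_soz=2, n_nsoz=2,
        phase_freq=3.0, amp_freq=120.0, kappa=0.8, snr_sd=1.0, seed=11,
    )


@pytest.fixture(scope="session")
def fast_spec():
    """Few surrogates for cheap unit tests (acceptance tests use 50-100)."""
    return SurrogateSpec(n_surrogates=30, min_shift=2000, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
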