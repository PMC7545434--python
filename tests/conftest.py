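import numpy as np
import pytest

from evokedlfp import Recording, SimConfig, simulate_recording

FS = 1000.0  # analysis-grade rate for fast tests; band edges stay far below Nyquist


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_config():
    """All stochastic sources off: trace is the analytic sum of EP waveforms."""
    return SimConfig(
        sampling_rate=FS,
        noise_sd=0.0,
        spontaneous_burst_rate=0.0,
        ep_amplitude=100.0,
        rng_seed=0,
    )


def stationary_config(seed: int, fs: float = FS, **kw) -> SimConfig:
    """Pure 1/f background: no EP, no bursts."""
    defaults = dict(
        sampling_rate=fs,
        noise_sd=15.0,
        spontaneous_burst_rate=0.0,
        ep_amplitude=0.0,
        rng_seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def stationary_recording(seed: int, condition: str = "A", **kw) -> Recording:
    return simulate_recording(stationary_config(seed, **kw), condition, f"s{seed}")
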