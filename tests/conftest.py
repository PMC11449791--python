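import numpy as np
import pytest

from hippoquant import BandSignals, LfpSimParams, generate_lfp


FS = 1000.0


def make_theta_bands(
    freq_hz: float = 8.0,
    amp: float = 3.0,
    duration_s: float = 60.0,
    low_amp: float = 0.05,
    fs: float = FS,
    seed: int = 0,
) -> BandSignals:
    """Hand-built band signals: a clean theta tone over a weak low band."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    theta = amp * np.sin(2 * np.pi * freq_hz * t)
    slow = low_amp * np.sin(2 * np.pi * 1.5 * t + rng.uniform(0, 2 * np.pi))
    return BandSignals(
        low=slow, theta=theta, supra=np.zeros(n), residual=np.zeros(n), fs_hz=fs
    )


@pytest.fixture(scope="session")
def theta_recording():
    """60 s movement-gated theta recording with ground truth."""
    return generate_lfp(LfpSimParams(duration_s=60.0, seed=42))


@pytest.fixture(scope="session")
def aperiodic_recording():
    """60 s aperiodic (no theta/gamma) recording, beta = 2.5."""
    return generate_lfp(
        LfpSimParams(duration_s=60.0, seed=7, theta_amp=0.0, gamma_rel=0.0)
    )
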