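import numpy as np
import pytest

from ecgcancel.signals import (
    Signal1D,
    SyntheticEcgSpec,
    generate_synthetic_audio,
    generate_synthetic_ecg,
)


@pytest.fixture(scope="session")
def ecg_default() -> Signal1D:
    """20 s of synthetic ECG at 500 Hz (n = 10^4)."""
    return generate_synthetic_ecg(SyntheticEcgSpec(seed=1))


@pytest.fixture(scope="session")
def audio_default(ecg_default) -> Signal1D:
    return generate_synthetic_audio(ecg_default.n, ecg_default.fs, seed=7)


@pytest.fixture()
def white_pair():
    """Two independent unit-variance white sources, n = 10^4."""
    rng = np.random.default_rng(0)
    n = 10_000
    return (
        Signal1D(rng.standard_normal(n), 500.0, "white-1"),
        Signal1D(rng.standard_normal(n), 500.0, "white-2"),
    )
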