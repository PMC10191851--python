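import numpy as np
import pytest

from gliocircuit.ecog import EpochSet, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(samples, fs=1200.0, tissue=None):
    n = samples.shape[0]
    return Recording(
        samples=samples,
        fs=fs,
        channel_ids=[f"ch{i}" for i in range(n)],
        channel_coords=np.zeros((n, 3)),
        tissue_label=tissue or ["unknown"] * n,
    )


def sinusoid_epochs(freq, fs=1200.0, amplitude=1.0):
    """One epoch, two antiphase channels (common average is a no-op)."""
    n = int(4 * fs)
    t = np.arange(n) / fs
    s = amplitude * np.sin(2 * np.pi * freq * t)
    return EpochSet(data=np.stack([np.stack([s, -s])]), fs=fs)


@pytest.fixture
def epoch_factory():
    return sinusoid_epochs


@pytest.fixture
def recording_factory():
    return make_recording
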