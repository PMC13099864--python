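import numpy as np
import pytest

from batnav.acoustics import Waveform, generate_broadcast
from batnav.receiver import ScatReceiver


@pytest.fixture(scope="session")
def broadcast():
    return generate_broadcast()


@pytest.fixture(scope="session")
def receiver(broadcast):
    return ScatReceiver(broadcast)


@pytest.fixture(scope="session")
def make_echo(broadcast):
    """Factory for synthetic echoes: delayed glint copies plus noise."""

    def _make(delays, amplitudes=None, noise=0.0, seed=0, n=16384):
        fs = broadcast.sample_rate
        freqs = np.fft.rfftfreq(n, 1 / fs)
        spec = np.fft.rfft(broadcast.samples, n)
        if amplitudes is None:
            amplitudes = [1.0] * len(delays)
        h = np.zeros_like(spec)
        for d, a in zip(delays, amplitudes):
            h = h + a * np.exp(-2j * np.pi * freqs * d)
        x = np.fft.irfft(spec * h, n)
        if noise > 0:
            x = x + np.random.default_rng(seed).normal(0, noise, n)
        return Waveform(x, fs)

    return _make
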