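import numpy as np
import pytest

from vocalearn.io_formats import Waveform
from vocalearn.synthetic_data import default_type_specs, generate_repertoire


def make_tone(freq: float, duration: float = 1.0, rate: int = 16000, amp: float = 0.5) -> Waveform:
    t = np.arange(int(round(duration * rate))) / rate
    return Waveform(amp * np.sin(2 * np.pi * freq * t), rate)


def make_harmonic_stack(
    f0: float, n_partials: int = 10, duration: float = 1.0, rate: int = 16000, amp: float = 0.5
) -> Waveform:
    t = np.arange(int(round(duration * rate))) / rate
    x = sum(np.sin(2 * np.pi * f0 * k * t) for k in range(1, n_partials + 1))
    return Waveform(amp * x / np.max(np.abs(x)), rate)


@pytest.fixture(scope="session")
def repertoire():
    """One shared synthetic two-type repertoire (60 + 45 calls, seed 42)."""
    spec1, spec2 = default_type_specs()
    fs, _ = generate_repertoire(spec1, spec2, 60, 45, seed=42)
    return fs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
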