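import numpy as np
import pytest

from pcg34.io import PCGRecord
from pcg34.synth import SynthConfig, generate_pcg

INTERIOR = slice_frac = 0.05


def interior(n: int, frac: float = 0.05) -> slice:
    """Slice excluding ``frac`` of the samples at each end (edge effects)."""
    k = int(frac * n)
    return slice(k, n - k)


@pytest.fixture(scope="session")
def s3_record():
    """One synthetic record with S3 planted in every cycle, plus its truth."""
    rec, truth = generate_pcg(SynthConfig(seed=11, s3_present=True))
    return rec, truth


@pytest.fixture(scope="session")
def s4_record():
    rec, truth = generate_pcg(SynthConfig(seed=111, s4_present=True))
    return rec, truth


@pytest.fixture
def tone_record():
    fs = 8000.0
    t = np.arange(0, 3, 1 / fs)
    return PCGRecord(np.cos(2 * np.pi * 50 * t), fs, "tone50")
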