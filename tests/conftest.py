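import numpy as np
import pytest

from ehgkit.io import EHGRecord
from ehgkit.synth import SynthSpec, generate_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_record(rng):
    """A tiny 7-channel record of plain noise (no bursts)."""
    return EHGRecord(rng.standard_normal((7, 400)) * 5.0, fs=20.0, subject_id="tiny")


@pytest.fixture(scope="session")
def short_synth():
    """A 10-minute synthetic record with 3 designed bursts, shared across tests."""
    spec = SynthSpec(duration_s=600.0, n_bursts=3, seed=42)
    return generate_record(spec)
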