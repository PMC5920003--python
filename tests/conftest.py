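import numpy as np
import pytest

from eapipe import generate_clip_set, generate_cohort
from eapipe.preprocessing import preprocess_streams
from eapipe.types import EffectSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clip_set():
    return generate_clip_set(16)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12 x 8 cohort with known truth, shared across tests (read-only)."""
    truth = EffectSpec(beta_condition=-0.2, beta_interaction=0.2)
    return generate_cohort(n_perceivers=12, n_clips=8, effects=truth, seed=99)


@pytest.fixture(scope="session")
def small_binned(small_cohort):
    return preprocess_streams(small_cohort.streams).binned
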