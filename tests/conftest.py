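import numpy as np
import pytest

from nirsdyn import SynthConfig, simulate_subject
from nirsdyn.connectivity import sliding_window_corr
from nirsdyn.preprocess import preprocess_chain


@pytest.fixture(scope="session")
def default_subject():
    """One full-length subject at generator defaults (seed 11)."""
    return simulate_subject(SynthConfig(seed=11), seed=11)


@pytest.fixture(scope="session")
def clean_hemo(default_subject):
    return preprocess_chain(default_subject.hemo)


@pytest.fixture(scope="session")
def default_drsfc(clean_hemo):
    return sliding_window_corr(clean_hemo, step_samples=10)


@pytest.fixture(scope="session")
def short_subject():
    """A cheap 120-s subject for structural (non-statistical) checks."""
    cfg = SynthConfig(duration_s=120.0, seed=3)
    return simulate_subject(cfg, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
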