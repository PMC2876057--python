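import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_dataset():
    """One study-like synthetic dataset shared across tests."""
    from sierrapop.simulate import make_study_like_dataset
    return make_study_like_dataset(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_alignment(seqs, populations=None, years=None):
    """Small helper: build an Alignment from raw sequence strings."""
    from sierrapop.sequences import Alignment, Record
    n = len(seqs)
    populations = populations or ["A"] * n
    years = years or [2000] * n
    return Alignment(records=[
        Record(f"s{i}", populations[i], years[i], seqs[i]) for i in range(n)])
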