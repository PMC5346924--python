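import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20171)


@pytest.fixture
def small_models():
    """A representative spread of small models for oracle comparisons."""
    from fragspace import PatternSpaceModel

    cases = []
    for T in (1, 2, 3, 5, 7, 10, 12):
        for lengths in ((2,), (3,), (2, 3), (3, 5), (2, 4, 5)):
            cases.append(PatternSpaceModel(T, lengths, read_length=2))
    return cases
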