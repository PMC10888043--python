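import numpy as np
import pytest

from petctsurv.survival import SurvivalTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_subject_table():
    """T=(1,2), both events: the hand-checkable partial-likelihood fixture."""
    return SurvivalTable(["a", "b"], [1.0, 2.0], [1, 1])


def random_survival_fixture(rng, n, with_censoring=True):
    times = rng.exponential(100.0, size=n) + 1.0
    if with_censoring:
        events = rng.integers(0, 2, size=n)
        if events.sum() == 0:
            events[rng.integers(n)] = 1
    else:
        events = np.ones(n, dtype=int)
    return SurvivalTable([f"s{i}" for i in range(n)], times, events)
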