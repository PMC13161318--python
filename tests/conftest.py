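import numpy as np
import pytest

from survclust import SoftAssignment, SurvivalCohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort():
    """Six subjects, mixed censoring, with one tied event time."""
    return SurvivalCohort(
        times=np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0]),
        events=np.array([1, 1, 0, 1, 0, 1]),
    )


def random_cohort(rng, n=None, k=2, censor_frac=None):
    """Random cohort + hard labels used across oracle comparisons."""
    n = n if n is not None else int(rng.integers(8, 50))
    censor_frac = (
        censor_frac if censor_frac is not None else float(rng.uniform(0, 0.5))
    )
    times = rng.exponential(1.0, n).round(3) + 0.01
    events = (rng.random(n) > censor_frac).astype(int)
    if events.sum() == 0:
        events[int(rng.integers(0, n))] = 1
    labels = rng.integers(0, k, n)
    # occupy every group so reference dof conventions agree
    labels[:k] = np.arange(k)
    return SurvivalCohort(times, events), labels


@pytest.fixture
def random_soft_assignment(rng):
    def make(n, k):
        return SoftAssignment(rng.dirichlet(np.ones(k), n))

    return make
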