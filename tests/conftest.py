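import numpy as np
import pytest

from bayeshaz import SurvivalDataset


def make_ds(time, event, group, tau=6.0):
    return SurvivalDataset(
        time=np.asarray(time, float),
        event=np.asarray(event, int),
        group=np.asarray(group, int),
        tau=tau,
    )


@pytest.fixture
def toy3():
    """Three subjects: events at 1 (group 0) and 2 (group 1), censored at 3."""
    return make_ds([1, 2, 3], [1, 1, 0], [0, 1, 1])


@pytest.fixture
def ten_row():
    """Fixed 10-subject two-group dataset with mixed censoring."""
    return make_ds(
        [0.5, 1.1, 1.7, 2.3, 2.9, 3.4, 3.9, 4.4, 5.0, 5.6],
        [1, 1, 0, 1, 1, 1, 0, 1, 1, 0],
        [0, 1, 0, 1, 0, 1, 1, 0, 1, 0],
    )


def random_dataset(rng, n=30, censor=0.3, tau=6.0):
    """Quick unstructured two-group sample for invariance checks."""
    time = np.minimum(rng.exponential(2.0, n), tau)
    event = (rng.random(n) > censor).astype(int)
    group = (np.arange(n) % 2).astype(int)
    return SurvivalDataset(time=time, event=event, group=group, tau=tau)
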