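import numpy as np
import pytest

from teadvice import ExpertPanel, LossSpec, TimeSeries, WeightScheme


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_expert_panel():
    """Expert 0 always advises 0, expert 1 always advises 1."""
    return ExpertPanel(np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]))


@pytest.fixture
def abs_loss():
    return LossSpec(kind="absolute", epsilon=1.0)


def random_instance(rng, n_max=8, t_max=10):
    """A random bounded-loss online-prediction instance."""
    n = int(rng.integers(2, n_max + 1))
    t = int(rng.integers(2, t_max + 1))
    panel = ExpertPanel(rng.uniform(0.0, 1.0, size=(n, t)))
    target = TimeSeries.from_values(rng.uniform(0.0, 1.0, size=t))
    return panel, target
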