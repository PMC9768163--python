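import numpy as np
import pytest

from soam.dynamics import ModelParams, PopulationState
from soam.networks import DirectedNetwork


@pytest.fixture
def tri_net():
    """Three nodes: 0 -> 1, 2 -> 1, 1 -> 2 (node 0 has no in-neighbors)."""
    return DirectedNetwork(3, frozenset({(0, 1), (2, 1), (1, 2)}))


@pytest.fixture
def complete3():
    return DirectedNetwork(3, frozenset({(a, b) for a in range(3) for b in range(3) if a != b}), "complete")


def make_state(opinions, is_amplifier=None, strikes=None, t=0):
    opinions = np.asarray(opinions, dtype=float)
    n = len(opinions)
    if is_amplifier is None:
        is_amplifier = np.zeros(n, dtype=bool)
    if strikes is None:
        strikes = np.zeros(n, dtype=np.int64)
    return PopulationState(opinions, np.asarray(is_amplifier, dtype=bool),
                           np.asarray(strikes, dtype=np.int64), t)


def small_params(**kw):
    defaults = dict(n=3, k=2, epsilon=0.5, pi=0.0, p=0.5, s=0.5, t_max=10)
    defaults.update(kw)
    return ModelParams(**defaults)
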