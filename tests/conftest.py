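import numpy as np
import pytest

from spikedeconv import SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def poisson_train(rate, duration, rng, label="u"):
    """Homogeneous Poisson train on a 1-ms grid (no refractoriness)."""
    n = int(round(duration / 0.001))
    idx = np.flatnonzero(rng.random(n) < rate * 0.001)
    return SpikeTrain(idx * 0.001, duration=duration, label=label)


@pytest.fixture
def poisson_pair(rng):
    return (
        poisson_train(5.0, 200.0, rng, "a"),
        poisson_train(8.0, 200.0, rng, "b"),
    )
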