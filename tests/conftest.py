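import numpy as np
import pytest

from fclandscape import OscillatorSpec, ParcellatedTimeseries, gen_oscillator_timeseries
from fclandscape.wsbm import Partition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ts(rng):
    """10 regions x 60 timepoints of smooth oscillatory signal."""
    ts, _ = gen_oscillator_timeseries(
        OscillatorSpec(n_regions=10, n_timepoints=60, seed=7)
    )
    return ts


def random_symmetric_adjacency(rng, n):
    a = rng.normal(size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def random_partition(rng, n, k):
    # ensure no singleton or empty community
    while True:
        labels = rng.integers(1, k + 1, size=n)
        counts = np.bincount(labels, minlength=k + 1)[1:]
        if (counts >= 2).all():
            return Partition(labels=labels, K=k)


def random_phase_stack(rng, n, t):
    from fclandscape.connectivity import DFCStack

    theta = rng.uniform(-np.pi, np.pi, size=(n, t))
    c, s = np.cos(theta), np.sin(theta)
    tensor = np.einsum("nt,pt->npt", c, c) + np.einsum("nt,pt->npt", s, s)
    return DFCStack(tensor=np.clip(tensor, -1, 1), phases=theta)
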