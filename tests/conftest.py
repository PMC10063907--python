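import numpy as np
import pytest

from nirsconn import BlockDesign, EffectSpec, make_default_probe, simulate_hb


@pytest.fixture(scope="session")
def probe():
    return make_default_probe()


@pytest.fixture(scope="session")
def design():
    return BlockDesign()


@pytest.fixture(scope="session")
def hb_scan(probe, design):
    """One default hemoglobin scan, shared read-only across tests."""
    return simulate_hb(design, EffectSpec(), probe, seed=12345)


@pytest.fixture(scope="session")
def region_indices(probe):
    pfc = probe.region_indices("PFC")
    m1 = probe.region_indices("M1_S1")
    return pfc, m1


def mean_block_r(net, idx_a, idx_b=None):
    """Mean network correlation within idx_a, or between idx_a and idx_b."""
    if idx_b is None:
        return np.mean([net.r[i, j] for i in idx_a for j in idx_a if i < j])
    return np.mean([net.r[i, j] for i in idx_a for j in idx_b])
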