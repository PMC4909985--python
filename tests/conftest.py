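import numpy as np
import pytest

from mosaicx.event_caller import CallerParams
from mosaicx.probe_model import ClusterBatch
from mosaicx.synthetic_data import SimulationConfig, make_probe_map


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    # 2000 probes over the chromosome ~= 13 probes/Mb, enough that a 5 Mb
    # candidate segment clears the 50-value mixture-fit precondition
    return SimulationConfig(seed=11, n_probes=2000, n_women=200)


@pytest.fixture(scope="session")
def probe_map(sim_config):
    return make_probe_map(sim_config.n_probes, sim_config)


@pytest.fixture(scope="session")
def batch0() -> ClusterBatch:
    return ClusterBatch(batch_id="batch0", lrr_baseline=0.0)


@pytest.fixture(scope="session")
def caller_params() -> CallerParams:
    # n_perm scaled down from the 1000 default to keep the suite fast;
    # still well above the 100-permutation validity floor
    return CallerParams(n_perm=200, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
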