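import numpy as np
import pytest

from homeoscan.io import SequenceRecord
from homeoscan.njtree import BootstrapConfig
from homeoscan.pipeline import PipelineConfig, run_pipeline
from homeoscan.search import QueryPool, ScanConfig, recursive_scan
from homeoscan.simulate import SimulationConfig, high_signal_config, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Reference synthetic dataset at the moderate-divergence defaults."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def scan_result(dataset):
    """Saturated recursive scan of the reference dataset's scaffolds."""
    profiles = dataset.root_profiles
    seeds = [SequenceRecord(f"seed|{k}", v) for k, v in sorted(profiles.items())]
    return recursive_scan(dataset.scaffolds, QueryPool.from_records(seeds),
                          ScanConfig(), profiles=profiles)


@pytest.fixture(scope="session")
def highsignal_run(tmp_path_factory):
    """Full pipeline run on the high-signal study conditions."""
    cfg = PipelineConfig(outdir=tmp_path_factory.mktemp("highsignal"), seed=1,
                         simulation=high_signal_config(),
                         bootstrap=BootstrapConfig(200))
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
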