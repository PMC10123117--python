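import numpy as np
import pytest

from ggsig.pipeline import default_config_for, run_pipeline
from ggsig.synthetic_data import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """Full synthetic input set at the default study conditions, seed 1."""
    out = tmp_path_factory.mktemp("sim")
    simulate_all(SimConfig(seed=1), out)
    return out


@pytest.fixture(scope="session")
def pipeline_out(sim_dir, tmp_path_factory):
    """Full pipeline run over the session synthetic inputs."""
    out = tmp_path_factory.mktemp("pipeline")
    manifest = run_pipeline(default_config_for(sim_dir), out)
    return out, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
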