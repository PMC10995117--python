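import numpy as np
import pytest

from vwmutil.config import RunConfig
from vwmutil.pipeline import run_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One small end-to-end pipeline run shared by output-shape tests."""
    out = tmp_path_factory.mktemp("small_run")
    cfg = RunConfig(
        seed=7,
        simulate={"n_subjects": 8, "trials_per_set_size": 10, "cd_trials": 40},
    )
    return cfg, run_pipeline(cfg, out_dir=out), out
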