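import numpy as np
import pytest

from icebloom import RunConfig, SimConfig
from icebloom.pipeline_io import run_pipeline
from icebloom.synthetic_data import generate_reference, generate_study


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, n_taxa=60, n_ref_samples=150, library_size=4000,
                     ecotype_pairs=3)


@pytest.fixture(scope="session")
def study(small_config):
    """(asv_table, meta, truth) for the session's small synthetic study."""
    return generate_study(small_config)


@pytest.fixture(scope="session")
def reference(small_config, study):
    asv_table, _, truth = study
    return generate_reference(small_config, asv_table, truth)


@pytest.fixture(scope="session")
def run_dir(tmp_path_factory):
    """A completed small pipeline run on disk."""
    out = tmp_path_factory.mktemp("run")
    sim = SimConfig(seed=11, n_taxa=50, n_ref_samples=120, library_size=3000)
    cfg = RunConfig(outdir=str(out), seed=11, n_permutations=99, top_n=10,
                    sim=sim)
    run_pipeline(cfg)
    return out, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
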