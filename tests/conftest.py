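import numpy as np
import pytest
from hypothesis import settings

from tmsmap.pipeline import RunConfig, run_pipeline
from tmsmap.synthetic import make_flat_patch_mesh, make_hemisphere_mesh

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def patch():
    """Fine flat patch with a precentral band, used across geometry tests."""
    return make_flat_patch_mesh(21, 21, 1.0, m1_band_mm=5.0)


@pytest.fixture(scope="session")
def hemisphere():
    return make_hemisphere_mesh(2, 10.0)


@pytest.fixture(scope="session")
def small_run():
    """One full pipeline run at reduced cohort size, shared by pipeline tests."""
    cfg = RunConfig(seed=7, n_subjects=3)
    return cfg, run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
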