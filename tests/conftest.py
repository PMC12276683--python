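import pytest

from helpers import small_config

from hybridscan.pipeline import run_pipeline
from hybridscan.simulate import simulate_all


@pytest.fixture(scope="session")
def small_cfg():
    return small_config(seed=1)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(TruthBundle, SR VariantSet, Pan VariantSet) for a small cohort."""
    return simulate_all(small_cfg)


@pytest.fixture(scope="session")
def small_pipeline():
    """One full pipeline replicate at the small scale."""
    return run_pipeline(small_config(seed=1))
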