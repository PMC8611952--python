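import pytest

from chemogenlib.config import DESK_SCALE, PipelineConfig
from chemogenlib.synthetic import generate_bundle, planted_optimum_pool


@pytest.fixture(scope="session")
def bundle():
    """One desk-scale synthetic study, shared across the session."""
    return generate_bundle(seed=1)


@pytest.fixture(scope="session")
def desk_cfg():
    return PipelineConfig(rng_seed=1, **DESK_SCALE)


@pytest.fixture(scope="session")
def planted_pool():
    """Candidate pool with a known perfect-coverage subset of 50."""
    return planted_optimum_pool(seed=7)
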