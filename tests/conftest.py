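import pytest
from hypothesis import HealthCheck, settings

from vdjannot.io_model import LocusConfig
from vdjannot.synthetic_locus import (
    default_motif_training,
    make_default_pwms,
    make_reference_set,
)

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config() -> LocusConfig:
    return LocusConfig()


@pytest.fixture(scope="session")
def pwms():
    return make_default_pwms()


@pytest.fixture(scope="session")
def training():
    return default_motif_training()


@pytest.fixture(scope="session")
def refset(config):
    return make_reference_set(seed=1, config=config)
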