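import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper module

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def uniform_prior():
    from altrsa import WorldPrior

    return WorldPrior.uniform(3)


@pytest.fixture(scope="session")
def alpha3_config():
    from altrsa import ModelConfig

    return ModelConfig(n=3, alpha=3.0)
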