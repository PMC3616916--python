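from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

from orphanaudit.synth import SimConfig

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down study conditions for fast end-to-end tests."""
    return replace(
        SimConfig(),
        seed=11,
        n_ests=300,
        n_random_probes=2000,
        n_families=400,
        probes_per_gene=3,
    )
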