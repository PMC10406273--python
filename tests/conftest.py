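import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_study():
    """A 4-network 16^3 study (3 control + 3 patient, T=8) shared across
    tests that only read it."""
    from parc5d.synthetic import SyntheticStudyConfig, simulate_study

    cfg = SyntheticStudyConfig.tiny(seed=5, n_control=3, n_patient=3,
                                    n_timepoints=8)
    return cfg, list(simulate_study(cfg))


@pytest.fixture(scope="session")
def small_templates():
    from parc5d.synthetic import SyntheticStudyConfig, make_network_templates

    cfg = SyntheticStudyConfig.small(seed=3)
    return cfg, make_network_templates(cfg)
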