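import numpy as np
import pytest

from sociallearn.synthetic_cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 44-subject cohort shared across read-only tests."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def zero_noise_config(**overrides) -> GeneratorConfig:
    """Generator config with every noise source silenced.

    The mediator-to-outcome leak is also zeroed so first-level estimates
    are exactly identified from the deterministic trial data.
    """
    base = dict(rating_noise_sd=0.0, esteem_noise_sd=0.0, t2_noise_sd=0.0,
                mediator_to_vas=0.0)
    base.update(overrides)
    return GeneratorConfig(**base)
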