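import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from orgproteome.records import AMINO_ACIDS
from orgproteome.simulate import GeneratorConfig, generate_proteome, generate_training_sets

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture(scope="session")
def small_training_sets():
    """Moderate-divergence training sets shared across classifier tests."""
    cfg = GeneratorConfig(seed=11, n_A=15, n_P=30, divergence=2.0)
    return generate_training_sets(cfg)


@pytest.fixture(scope="session")
def tiny_proteome():
    cfg = GeneratorConfig(seed=7, n_A=5, n_P=5, n_tm=5, n_cyt=5, divergence=2.0)
    return generate_proteome(cfg)
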