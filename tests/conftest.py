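import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vedopk.data import apply_exclusions
from vedopk.model import ModelParams
from vedopk.trial import PopulationSpec, generate_population, simulate_trial

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def truth() -> ModelParams:
    """The published final model, used as simulation truth throughout."""
    return ModelParams()


@pytest.fixture(scope="session")
def small_dataset(truth):
    """~25-subject mixed-design trial with BLQ records excluded."""
    pop = generate_population(PopulationSpec(n_vedo_1015=5, n_vedo_3035=20), seed=11)
    ds = simulate_trial(pop, truth, seed=12)
    retained, _ = apply_exclusions(ds)
    return retained


@pytest.fixture(scope="session")
def medium_dataset(truth):
    """~60-subject mixed-design trial for diagnostics tests."""
    pop = generate_population(PopulationSpec(n_vedo_1015=10, n_vedo_3035=50), seed=21)
    ds = simulate_trial(pop, truth, seed=22)
    retained, _ = apply_exclusions(ds)
    return retained


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
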