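import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects x 5 measurements, generated once per session."""
    from oscillobp.cohort import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_subjects=12, seed=3))


@pytest.fixture(scope="session")
def tiny_train_config():
    from oscillobp.dbn import TrainConfig

    return TrainConfig(
        epochs_pretrain=10, epochs_finetune=40, ensemble_size=2, seed=5
    )
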