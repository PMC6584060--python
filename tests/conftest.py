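import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cpgsig as c
from cpgsig.models import ModelConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# reduced MLP epoch budget keeps fit-heavy tests fast; everything else at defaults
CHEAP = ModelConfig(mlp_max_iter=60)


@pytest.fixture(scope="session")
def cheap_config():
    return CHEAP


@pytest.fixture(scope="session")
def strong_instance():
    """Synthetic instance with 10 strongly planted CpGs (logit separation ~7.5 sd)
    among 2,000 nulls, plus the default coverage fold plan on its 58 samples."""
    matrix, cohort, planted = c.generate(
        c.SyntheticSpec(
            n_per_class=29, n_features=2000, n_informative=10,
            effect_delta=3.0, noise_sd=0.4, seed=1,
        )
    )
    plan = c.make_fold_plan(cohort, 8, (40, 10, 8), seed=3)
    return matrix, cohort, planted, plan


@pytest.fixture(scope="session")
def tiny_instance():
    """Small all-planted instance for fast model-level tests."""
    matrix, cohort, planted = c.generate(
        c.SyntheticSpec(
            n_per_class=29, n_features=12, n_informative=4,
            effect_delta=4.0, noise_sd=0.4, seed=2,
        )
    )
    plan = c.make_fold_plan(cohort, 8, (40, 10, 8), seed=5)
    return matrix, cohort, planted, plan


def balanced_cohort(n_per_class: int, n_neither: int = 0) -> c.LabeledCohort:
    ids = (
        [f"A{i}" for i in range(n_per_class)]
        + [f"S{i}" for i in range(n_per_class)]
        + [f"N{i}" for i in range(n_neither)]
    )
    labels = (
        [c.ALLERGIC] * n_per_class + [c.SENSITIZED] * n_per_class + [c.NEITHER] * n_neither
    )
    return c.LabeledCohort(tuple(ids), tuple(labels))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
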