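import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from benthic_encounters import GeneratorConfig, HollingParams
from benthic_encounters.synthetic_data import generate_trials, geometric_levels


@pytest.fixture(scope="session")
def type2_trials():
    """Strong-signal type-II depletion experiment (6 levels x 25 reps)."""
    params = HollingParams(b=0.5, h=0.1, q=0.0)
    return params, generate_trials(params, geometric_levels(6), 25, 1.0, 42,
                                   pair_id="t2")


@pytest.fixture(scope="session")
def type3_trials():
    """Strong-signal type-III depletion experiment."""
    params = HollingParams(b=0.25, h=0.1, q=1.0)
    return params, generate_trials(params, geometric_levels(6), 25, 1.0, 43,
                                   pair_id="t3")


@pytest.fixture(scope="session")
def small_meta():
    """Small synthetic meta-dataset with its generating truth."""
    from benthic_encounters import generate_meta_dataset
    cfg = GeneratorConfig(seed=7, n_pairs=12, replicates_per_level=8)
    return generate_meta_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
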