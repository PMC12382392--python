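import numpy as np
import pytest

from nitroscan.pipeline import RunConfig, run_all
from nitroscan.synthetic import ExperimentConfig, generate_experiment


@pytest.fixture(scope="session")
def small_config():
    """Reduced experiment (12 plants, small rasters/clouds) for fast tests."""
    return ExperimentConfig(
        seed=7,
        doses_ppm=(20, 80, 160, 400),
        replicates_per_dose=(3, 3, 3, 3),
        image_size=64,
        cloud_points=600,
        background_noise_points=15,
    )


@pytest.fixture(scope="session")
def small_plants(small_config):
    return generate_experiment(small_config)


@pytest.fixture(scope="session")
def seed_panel():
    """Twenty full-size (84-plant) pipeline runs for majority-vote properties.

    Relevance is trimmed to one iteration: the panel's consumers only use the
    metric grid and the feature correlation matrix.
    """
    results = []
    for seed in range(20):
        res = run_all(RunConfig(seed=seed, relevance_iterations=1))
        results.append(res)
    return results


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
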