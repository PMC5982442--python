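import numpy as np
import pytest

from monoflux import (
    ExperimentConfig,
    PipelineConfig,
    generate_experiment,
    ground_truth,
    run_pipeline,
)


@pytest.fixture(scope="session")
def default_config() -> ExperimentConfig:
    return ExperimentConfig(seed=1234)


@pytest.fixture(scope="session")
def zero_noise_config() -> ExperimentConfig:
    return ExperimentConfig(seed=99).zero_noise()


@pytest.fixture(scope="session")
def zero_noise_result(zero_noise_config):
    return run_pipeline(PipelineConfig(synthetic=zero_noise_config, run_stats=False))


@pytest.fixture(scope="session")
def default_result(default_config):
    return run_pipeline(
        PipelineConfig(synthetic=default_config, run_stats=True, n_perm=499, seed=5)
    )


@pytest.fixture(scope="session")
def default_truth(default_config):
    return ground_truth(default_config)


@pytest.fixture(scope="session")
def experiment(default_config):
    return generate_experiment(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
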