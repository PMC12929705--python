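import numpy as np
import pytest

from cytotraits.synthio import SynthConfig
from cytotraits.pipeline import RunConfig, run_culture_analysis, run_field_assessment


@pytest.fixture
def small_config() -> SynthConfig:
    """Small but gateable synthetic experiment."""
    return SynthConfig(n_events_per_sample=1500, n_field_samples=6, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def demo_run_config() -> RunConfig:
    """The full 5x4 design with a 28-sample field series, shared across tests."""
    return RunConfig(
        synth=SynthConfig(n_events_per_sample=1200, n_field_samples=28, seed=7),
        seed=7,
    )


@pytest.fixture(scope="session")
def culture_results(demo_run_config):
    return run_culture_analysis(demo_run_config)


@pytest.fixture(scope="session")
def field_results(demo_run_config, culture_results):
    return run_field_assessment(demo_run_config, culture_results)
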