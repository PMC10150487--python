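import pytest

from readerstab.config import PipelineConfig, SimulationConfig
from readerstab.simulate import make_annotation


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(
        n_genes=40,
        seed=7,
        depth_per_sample=2e5,
        polya_depth_per_sample=2e5,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def config():
    return small_config()


@pytest.fixture(scope="session")
def annotation(config):
    return make_annotation(config)


@pytest.fixture(scope="session")
def pipeline_config(config):
    return PipelineConfig(seed=config.seed, simulation=config)
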