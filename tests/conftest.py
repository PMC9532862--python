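import pytest

import cernet


@pytest.fixture(scope="session")
def default_config() -> cernet.SimulationConfig:
    return cernet.SimulationConfig()


@pytest.fixture(scope="session")
def fixture_bundle(default_config):
    """The default seed-42 simulated study (counts, design, truth, sequences)."""
    return cernet.simulate_all(default_config)


@pytest.fixture(scope="session")
def pipeline_result():
    """End-to-end pipeline run on the default seed-42 fixture."""
    return cernet.run_pipeline(cernet.PipelineConfig())
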