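import pytest

from symbioflux import (
    PipelineConfig,
    ToySymbiosisSpec,
    generate_toy_symbiosis,
    run_pipeline,
)


@pytest.fixture(scope="session")
def default_bundle():
    """Default toy symbiosis: glucose-limited, cross-feed and vitamin on."""
    return generate_toy_symbiosis(ToySymbiosisSpec(seed=7))


@pytest.fixture(scope="session")
def integrated_model(default_bundle):
    return default_bundle.integrate()


@pytest.fixture(scope="session")
def pipeline_result():
    """One full pipeline run on the default toy symbiosis, reused read-only."""
    return run_pipeline(PipelineConfig(toy=True, seed=7))
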