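import pytest

from lncvsd.synthetic import SimulationConfig, generate_annotation


@pytest.fixture(scope="session")
def planted_genome():
    """Default-sized synthetic genome with ground-truth class labels."""
    config = SimulationConfig(seed=11)
    annotation, truth = generate_annotation(config)
    return config, annotation, truth
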