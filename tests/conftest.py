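import pytest

from dgescreen.simulate import (
    SimulationConfig,
    generate_expression_matrix,
    generate_unigenes,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Noise-free small experiment used by several integration tests."""
    return SimulationConfig(
        n_unigenes=200,
        length_range=(200, 800),
        library_depth=50_000,
        specific_fraction_per_stage=0.10,
        base_error_rate=0.0,
        n_contamination_rate=0.0,
        singleton_noise_rate=0.0,
        catg_guarantee_fraction=1.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    unigenes = generate_unigenes(small_config)
    truth = generate_expression_matrix(small_config, unigenes)
    return unigenes, truth
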