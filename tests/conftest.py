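import pytest

from triadnet.synthetic import SyntheticConfig, generate_benchmark


@pytest.fixture(scope="session")
def small_config():
    """A reduced benchmark: 80 positives, 5:1 negatives, fast to predict on."""
    return SyntheticConfig(
        n_reaction_templates=8,
        triads_per_template=10,
        negative_ratio=5,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_benchmark(small_config):
    return generate_benchmark(small_config)


@pytest.fixture(scope="session")
def default_benchmark():
    cfg = SyntheticConfig(seed=1)
    return cfg, generate_benchmark(cfg)
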