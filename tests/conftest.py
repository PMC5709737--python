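import pytest

from shoremap import benchmark
from shoremap.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale genome for fast unit tests."""
    return SyntheticConfig(
        seed=5, n_chroms=2, chrom_length_bp=1_000_000,
        n_islands=6, n_genes=10, n_lmrs=4,
    )


@pytest.fixture(scope="session")
def default_run():
    """The default study-condition fixture, fully analyzed once per session."""
    return benchmark.run_fixture(SyntheticConfig())


@pytest.fixture(scope="session")
def small_run(small_config):
    return benchmark.run_fixture(small_config)
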