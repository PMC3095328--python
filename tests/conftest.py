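import pytest

from bacpool import simdata


@pytest.fixture(scope="session")
def toy_genome():
    """100 kb genome at study-like gene density and composition."""
    return simdata.make_genome(100_000, 10, 0.05, 0.33, seed=1)


@pytest.fixture(scope="session")
def gene_only_genome():
    """Genome without TEs, convenient for synteny construction."""
    return simdata.make_genome(100_000, 10, 0.0, 0.33, seed=1)


@pytest.fixture(scope="session")
def small_pool(toy_genome):
    return simdata.make_bac_pool(
        toy_genome, 2, insert_mean=30_000, insert_sd=2_000, seed=3
    )
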