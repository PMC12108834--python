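import pytest

from tcnescan.simulate import simulate_coverage, simulate_genome


@pytest.fixture(scope="session")
def toy_fixture():
    """Small planted genome shared by read-only tests."""
    return simulate_genome(
        n_chroms=2, chrom_length=400_000, n_genes=16, n_cnes=80, seed=7
    )


@pytest.fixture(scope="session")
def toy_coverage(toy_fixture):
    return simulate_coverage(toy_fixture, n_samples=10, seed=70)
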