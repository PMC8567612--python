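import numpy as np
import pytest

from achiasma import DivergenceProfile, GenomeSpec, simulate_parent_pair


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    """Two short chromosomes with a masked block and off-center centromeres."""
    return GenomeSpec(
        chromosomes=(("chr1", 300_000), ("chr2", 200_000)),
        gc_content=0.296,
        masked_intervals={"chr1": [(140_000, 160_000)]},
        centromeres={"chr1": 50_000, "chr2": 100_000},
    )


@pytest.fixture(scope="session")
def dense_pair(small_genome):
    """A parental pair with ~1 marker / 500 bp on the small genome."""
    profile = DivergenceProfile.uniform(small_genome, 0.002)
    return simulate_parent_pair(small_genome, profile, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
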