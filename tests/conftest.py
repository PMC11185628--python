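import numpy as np
import pytest

from admixmate import GenomeMap, Individual, SimConfig, TractSet

SMALL_CHROMS = [50_000_000, 50_000_000]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_gmap():
    """Two 50 Mb chromosomes at the default rate: 1 crossover expected."""
    return GenomeMap(chrom_lengths=np.array(SMALL_CHROMS), recomb_rate=1e-8)


@pytest.fixture
def default_gmap():
    return GenomeMap()


@pytest.fixture
def mixed_parent(small_gmap):
    """hap1 entirely source 1, hap2 entirely source 2 (x = 0.5)."""
    return Individual(
        hap1=TractSet.single_source(1, small_gmap),
        hap2=TractSet.single_source(2, small_gmap),
        x=0.5,
        group="A",
        is_migrant=False,
        id=0,
    )


def small_config(**overrides):
    """Reduced-size config used across tests: tiny census, 100 Mb genome."""
    defaults = dict(
        n=200,
        generations=2,
        kind="random",
        alpha=1.0,
        chrom_lengths=SMALL_CHROMS,
        seed=7,
        snapshot_generations=(),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
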