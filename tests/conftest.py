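import numpy as np
import pytest

from bsakit import simdata


@pytest.fixture(scope="session")
def one_chrom_config():
    """A single 50-Mb chromosome carrying the causal locus at 40 Mb."""
    return simdata.SimConfig(
        chromosomes=(("5A", 50_000_000),),
        causal_locus=("5A", 40_000_000),
        n_f2=400,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_population(one_chrom_config):
    return simdata.simulate_f2_population(one_chrom_config)


@pytest.fixture(scope="session")
def small_bulks(one_chrom_config, small_population):
    return simdata.build_bulks(small_population, one_chrom_config.bulk_size, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
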