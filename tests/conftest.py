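import pytest

from delscan import (
    SimConfig,
    make_synthetic_construct,
    simulate_counts,
)


@pytest.fixture(scope="session")
def toy_construct():
    """A 20-residue synthetic dual-allele construct, fixed seed."""
    return make_synthetic_construct(20, seed=11)


@pytest.fixture(scope="session")
def mid_construct():
    """A 30-residue construct used for read-level simulations."""
    return make_synthetic_construct(30, seed=7)


@pytest.fixture(scope="session")
def planted_sim(mid_construct):
    """Count-level simulation with a planted dispensable domain at codons 8-15."""
    config = SimConfig(
        protein_length=30,
        seed=42,
        domains=[(8, 15)],
        survival_inside=1.0,
        survival_outside=0.02,
        reads_per_allele=200,
        n_replicates=3,
    )
    return simulate_counts(mid_construct, config)
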