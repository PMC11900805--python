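import pytest

from secircuit.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, shared across tests (seed 0)."""
    return simulate_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast end-to-end checks."""
    config = SimConfig(
        n_samples=6,
        n_chroms=2,
        chrom_length=500_000,
        n_recurrent_ses=9,
        n_private_ses=1,
        n_typical_peaks=15,
        n_genes=400,
        n_de_genes=30,
        seed=11,
    )
    return simulate_cohort(config)
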