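import numpy as np
import pytest

from invkaryo.simulate import SimConfig, simulate_inversion_genotypes


@pytest.fixture(scope="session")
def study_sim():
    """One simulated chromosome at the default study conditions."""
    cfg = SimConfig(seed=7)
    return simulate_inversion_genotypes(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Fully diagnostic inversion without gene flux (sharp clusters)."""
    cfg = SimConfig(
        n_individuals=500, n_snps=100, class_freqs=(0.5, 0.5),
        breakpoint_divergence=1.0, gene_flux_rate=0.0, seed=11,
    )
    return simulate_inversion_genotypes(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
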