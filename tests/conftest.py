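import numpy as np
import pytest

from cldla import SimConfig, simulate_population


TINY_KW = dict(n_founders=20, n_generations=4, n_snps=300,
               chrom_length_bp=30_000_000, disease_bp=15_000_000,
               study_composition={"affected": 8, "carrier": 8, "free": 20},
               phenocopy_count=2, missing_rate=0.01, trio_fraction=0.3,
               n_background_variants=100)


@pytest.fixture(scope="session")
def tiny_sim():
    """Small simulated study reused across unit tests (seed fixed)."""
    return simulate_population(SimConfig(seed=11, **TINY_KW))


@pytest.fixture(scope="session")
def tiny_sim_complete():
    """Like tiny_sim but without missing genotypes (for phasing truth)."""
    kw = dict(TINY_KW, missing_rate=0.0)
    return simulate_population(SimConfig(seed=11, **kw))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
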