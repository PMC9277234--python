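import numpy as np
import pytest

from symbiopleio.config import SimConfig
from symbiopleio.gwas import compute_kinship, filter_variants
from symbiopleio.simulate import simulate_genotypes


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A compact null panel config reused across unit tests."""
    return SimConfig(
        n_strains=40,
        n_sites=300,
        n_subpops=3,
        seed=42,
        n_concordant_pairs=0,
        n_discordant_pairs=0,
        missing_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    panel, _ = filter_variants(simulate_genotypes(small_cfg), 0.05, 0.2)
    return panel


@pytest.fixture(scope="session")
def small_kinship(small_panel):
    return compute_kinship(small_panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
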