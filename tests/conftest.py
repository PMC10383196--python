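import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from svrgwas import SimConfig, simulate_genotypes, simulate_phenotypes  # noqa: E402


@pytest.fixture(scope="session")
def small_panel():
    """100 genotypes x 500 SNPs with 5 planted QTL, complete calls."""
    cfg = SimConfig(n_genotypes=100, n_snps=500, n_chromosomes=10, seed=11)
    gm, _ = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(gm, cfg, seed=12)
    return gm, pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
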