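import logging

import pytest

from aelink.pipeline import run_discovery
from aelink.simulate import SimConfig, simulate_study

logging.getLogger("aelink").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_study():
    """One default-sized synthetic study shared across tests."""
    return simulate_study(seed=1)


@pytest.fixture(scope="session")
def discovery(default_study):
    """Full discovery pipeline run on the default study."""
    return run_discovery(default_study)


@pytest.fixture(scope="session")
def recovery_study():
    """Planted-effect regime used for sensitivity/precision checks:
    |LFC| = 2 with 30 patient pairs and strongly correlated planted links."""
    cfg = SimConfig(
        seed=11,
        n_pairs_rnaseq=30,
        n_chroms=2,
        chrom_length=6_000_000,
        n_genes=120,
        n_enhancers=400,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def recovery_discovery(recovery_study):
    return run_discovery(recovery_study, with_methylation=False)
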