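import numpy as np
import pytest

from oligoheart.simulate import CohortConfig, gene_names, simulate_trio_cohort


@pytest.fixture(scope="session")
def small_noiseless_cohort():
    """12+12 trios, 3000 sites, background silenced so only planted events
    can pass the consequence filter."""
    cfg = CohortConfig(
        seed=7,
        n_case_trios=12,
        n_control_trios=12,
        n_sites=3_000,
        planted_genes=tuple(gene_names(8)),
        rate_denovo=0.5,
        rate_comphet=0.4,
        rate_rarehom=0.3,
        rate_comphet_cis=0.2,
    ).noiseless()
    return simulate_trio_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
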