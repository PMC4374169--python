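import numpy as np
import pytest

from haplomix.scenarios import (bloc_scenario, run_recovery, standard_scenario)
from haplomix.simulate import DonorPoolSpec, simulate_donor_pool


@pytest.fixture(scope="session")
def small_pool():
    """Small structured donor pool: 3 pops x 12 haps, 200 SNPs, 4 chroms."""
    spec = DonorPoolSpec(
        n_pops=3, haps_per_pop=12, n_sites=200,
        chrom_lengths_morgans=[0.1] * 4, divergence=0.2, seed=11,
        bg_copy_rate=30.0,
    )
    return simulate_donor_pool(spec)


@pytest.fixture(scope="session")
def standard_run():
    """Standard 3-population admixture scenario, painted and decomposed."""
    sc = standard_scenario(seed=1)
    return sc, run_recovery(sc, em=True, jackknife=True, individual_level=True)


@pytest.fixture(scope="session")
def surrogate_run():
    """Standard scenario plus a masked, unadmixed surrogate population."""
    sc = standard_scenario(seed=1, with_surrogate=True)
    return sc, run_recovery(sc, em=True)


@pytest.fixture(scope="session")
def bloc_run():
    """Two recipient blocs with disjoint European donor usage."""
    sc = bloc_scenario(seed=2)
    return sc, run_recovery(sc, em=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
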