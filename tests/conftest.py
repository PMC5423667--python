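import warnings

import numpy as np
import pytest

import skagerrak as sk


@pytest.fixture(scope="session")
def six_pop_table() -> sk.GenotypeTable:
    """Study-shaped synthetic cohort: 6 populations (n=12,50,...), 6 loci."""
    return sk.simulate_genotypes(sk.GenoSimConfig(seed=3), seed=3)


@pytest.fixture(scope="session")
def two_pop_null_table() -> sk.GenotypeTable:
    """Two panmictic samples drawn from identical allele frequencies."""
    cfg = sk.GenoSimConfig(
        pop_names=["P1", "P2"], sizes=[50, 50], F=0.0, missing_rate=0.0, n_alleles=8
    )
    return sk.simulate_genotypes(cfg, seed=11)


@pytest.fixture(scope="session")
def warm_scenario():
    return sk.generate_ocean_scenario(preset="warm")


@pytest.fixture(scope="session")
def cold_scenario():
    return sk.generate_ocean_scenario(preset="cold")


@pytest.fixture
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def tiny_table(calls, pops=None, loci=None) -> sk.GenotypeTable:
    """Hand-made table from a nested list of (a, b) pairs per individual."""
    arr = np.asarray(calls, dtype=np.int64)
    n, L = arr.shape[0], arr.shape[1]
    pops = pops or ["P"] * n
    loci = loci or [f"L{j + 1}" for j in range(L)]
    return sk.GenotypeTable([f"i{k}" for k in range(n)], list(pops), list(loci), arr)
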