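import numpy as np
import pytest

from mhcdemekit.core import AlleleCatalog
from mhcdemekit.synthdata import SimConfig, simulate_metapopulation


@pytest.fixture(scope="session")
def small_config():
    """A compact metapopulation: fast enough for per-test simulation."""
    return SimConfig(
        n_regions=2, demes_per_region=2, individuals_per_deme=(5, 8),
        n_ancestral_alleles=8, loci={"H2-Aa": 208},
        reads_per_individual=(60, 80), seed=101)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_metapopulation(small_config)


@pytest.fixture(scope="session")
def default_truth():
    """The full default study design (2 regions x 5 demes x ~10 animals)."""
    return simulate_metapopulation(SimConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ancestral_catalog(default_truth):
    cat = AlleleCatalog()
    for locus, d in default_truth.alleles.items():
        for a in d.values():
            if a.class_label == "shared":
                cat.new_entry(locus, a.sequence, status="known")
    return cat
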