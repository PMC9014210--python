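import numpy as np
import pandas as pd
import pytest

from invamicro.io_formats import CountTable
from invamicro.simdata import SimConfig, simulate_dataset


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """A scaled-down study design used throughout the unit tests."""
    base = dict(
        seed=seed, n_rivers=3, sites_per_river=(2, 2, 2),
        native_species=("sp1", "sp2"), invasive_per_site=3,
        natives_per_site=2, n_asvs=80, n_snps=400, n_monomorphic=300,
        n_pathways=24, n_compounds=16, n_chromosomes=3,
        depth_lognormal_mean=7.6, env_depth_lognormal_mean=7.2,
        n_indel_sites=10, n_triallelic_sites=8, n_lowqual_sites=8,
        n_highmissing_sites=8,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def sim_dataset():
    return simulate_dataset(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_table(counts: np.ndarray, sample_ids=None, feature_ids=None,
               sites=None, species=None, host_types=None,
               rivers=None) -> CountTable:
    """Build a CountTable with minimal metadata for unit tests."""
    n, m = counts.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    feature_ids = feature_ids or [f"f{j}" for j in range(m)]
    md = pd.DataFrame({
        "host_species": species or ["spX"] * n,
        "site": sites or ["siteA"] * n,
        "river": rivers or ["river1"] * n,
        "host_type": host_types or ["native_mussel"] * n,
    }, index=sample_ids)
    return CountTable(pd.DataFrame(np.asarray(counts, dtype=np.int64),
                                   index=sample_ids, columns=feature_ids),
                      md)
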