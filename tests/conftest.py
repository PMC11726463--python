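import numpy as np
import pandas as pd
import pytest

from taxodelim import gendist, synth, traitevol


@pytest.fixture(scope="session")
def small_sim():
    """One small continuous-population simulation shared across tests."""
    cfg = synth.SpatialSimConfig(n_windows=6, snps_per_window=50, seed=123)
    gws, meta = synth.simulate_spatial_genotypes(cfg)
    return gws, meta


@pytest.fixture(scope="session")
def small_dist(small_sim):
    gws, meta = small_sim
    return gendist.distance_records(gws, meta), meta


@pytest.fixture(scope="session")
def yule15():
    """15-tip depth-1 pure-birth tree used by the trait-evolution tests."""
    return traitevol.tree_info(synth.simulate_pure_birth_tree(15, depth=1.0, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def bm_dataset(tree, seed, root=10.0, sigma2=1.0):
    """One univariate BM draw of species means on a tree."""
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    L = np.linalg.cholesky(sigma2 * tree.shared_time + 1e-12 * np.eye(n))
    y = root + L @ rng.standard_normal(n)
    return pd.DataFrame({"trait": y}, index=tree.tips)
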