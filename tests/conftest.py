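import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cellatlas import synthetic
from cellatlas.core import UmiMatrix


@pytest.fixture(scope="session")
def small_config():
    return synthetic.AtlasSimConfig(
        n_species=2,
        n_clusters=4,
        n_genes=200,
        n_marker_genes_per_cluster=10,
        cells_per_replicate=120,
        phenotypes={"w": 2, "q": 2},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return synthetic.simulate_atlas(small_config)


def umi_from_dense(counts, genes=None, **obs_cols):
    """Small helper: dense array → UmiMatrix with generated ids."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = pd.Index(genes if genes is not None else [f"g{j}" for j in range(n_genes)])
    obs = pd.DataFrame(index=pd.Index([f"cell{i}" for i in range(n_cells)], name="cell"))
    for key, values in obs_cols.items():
        obs[key] = list(values)
    return UmiMatrix(sp.csr_matrix(counts), genes, obs)


@pytest.fixture
def umi_factory():
    return umi_from_dense
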