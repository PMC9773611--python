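import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import tmekit as tk


def make_adata(counts, mito_flags=None, obs=None, gene_names=None, cell_names=None):
    """Small hand-built AnnData (cells x genes, sparse counts)."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = gene_names or [f"g{i}" for i in range(n_genes)]
    cells = cell_names or [f"c{i}" for i in range(n_cells)]
    var = pd.DataFrame(
        {"mito": mito_flags if mito_flags is not None else [False] * n_genes},
        index=genes,
    )
    obs_df = pd.DataFrame(index=cells)
    if obs:
        for k, v in obs.items():
            obs_df[k] = v
    return ad.AnnData(X=sp.csr_matrix(counts.astype(float)), obs=obs_df, var=var)


@pytest.fixture(scope="session")
def clustering_cohort():
    cfg = tk.synthetic.clustering_cohort_config(seed=7)
    adata, truth = tk.generate_cohort(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def clustering_norm(clustering_cohort):
    _, adata, _ = clustering_cohort
    return tk.normalize(adata)


@pytest.fixture(scope="session")
def hub_cohort():
    cfg = tk.synthetic.hub_cohort_config(seed=11)
    adata, truth = tk.generate_cohort(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def hub_norm(hub_cohort):
    _, adata, _ = hub_cohort
    return tk.normalize(adata)


@pytest.fixture(scope="session")
def artifact_cohort():
    cfg = tk.synthetic.artifact_cohort_config(seed=3)
    adata, truth = tk.generate_cohort(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def bicluster_cohort():
    cfg = tk.synthetic.bicluster_cohort_config(seed=5)
    adata, truth = tk.generate_cohort(cfg)
    return cfg, adata, truth
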