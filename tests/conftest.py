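import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from txhyper import QCParams, SimConfig, apply_qc, normalize_log, simulate_dataset


def make_adata(counts, gene_ids=None, tissue=None, normalized=None, cluster=None, phase=None):
    """Build a minimal AnnData from a dense count array for toy tests."""
    counts = np.asarray(counts)
    n, g = counts.shape
    gene_ids = gene_ids or [f"g{j + 1}" for j in range(g)]
    obs = pd.DataFrame(index=[f"r{i + 1}" for i in range(n)])
    obs["cell_id"] = obs.index
    obs["tissue"] = tissue if tissue is not None else ["FT"] * n
    obs["cluster"] = cluster if cluster is not None else ["c0"] * n
    obs["phase"] = phase if phase is not None else ["secretory"] * n
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int32)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene")),
    )
    if normalized is not None:
        adata.layers["normalized"] = np.asarray(normalized, dtype=float)
    return adata


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated two-tissue dataset, QC'd and normalized."""
    cfg = SimConfig(
        n_cells_per_group=150,
        n_genes=500,
        n_clusters=2,
        de_genes=50,
        de_log2fc=1.5,
        module_sizes=(60,),
        module_rho=0.7,
        hub_genes=2,
        dropout_rate=0.05,
        seed=42,
    )
    adata = simulate_dataset(cfg)
    adata, _ = apply_qc(adata, QCParams(min_genes_per_cell=10, min_cells_per_gene=3))
    return normalize_log(adata)
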