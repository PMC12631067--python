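import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from orthatlas import SimConfig, merge_atlases, simulate_dual_atlas
from orthatlas.preprocess import filter_cells_genes, normalize_log

SMALL_CFG = SimConfig(
    n_types=4, cells_per_type_per_species=50, n_ortholog_pairs=500, seed=7
)


def make_adata(counts, cell_types=None, species="human", layer="raw", gene_ids=None):
    """Dense counts (cells x genes) -> AnnData with standard metadata."""
    counts = np.asarray(counts)
    n, g = counts.shape
    if gene_ids is None:
        gene_ids = [f"{species[:3]}:G{i:04d}" for i in range(1, g + 1)]
    obs = pd.DataFrame(
        {
            "species": species,
            "sex": [("XX", "XY")[i % 2] for i in range(n)],
            "stage": "s1",
            "cell_type": cell_types if cell_types is not None else ["t"] * n,
        },
        index=[f"{species}-c{i}" for i in range(n)],
    )
    var = pd.DataFrame(
        {"gene_symbol": [x.split(":")[-1] for x in gene_ids]},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    ad = AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    ad.uns["layer"] = layer
    ad.uns["species"] = species
    return ad


@pytest.fixture(scope="session")
def small_sim():
    return simulate_dual_atlas(SMALL_CFG)


@pytest.fixture(scope="session")
def merged_small(small_sim):
    a, b, omap, truth = small_sim
    a = filter_cells_genes(a)
    b = filter_cells_genes(b)
    merged = normalize_log(merge_atlases(a, b, omap))
    return merged, omap, truth
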