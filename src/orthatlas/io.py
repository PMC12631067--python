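"""Reading and writing the on-disk atlas layout.

One species' matrix is stored 10x-style as an uncompressed MatrixMarket
triplet — ``matrix.mtx`` (genes x cells, integer), ``features.tsv``
(gene_id, gene_symbol), ``barcodes.tsv`` — plus ``cells.tsv`` with per-cell
metadata (barcode, species, sex, stage, cell_type).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

_META_COLS = ["species", "sex", "stage", "cell_type"]


def write_atlas(matrix: AnnData, directory: str | Path) -> None:
    """Write an atlas directory; errors on an empty matrix."""
    if matrix.n_obs == 0 or matrix.n_vars == 0:
        raise ValueError("refusing to write an empty matrix (0 cells or 0 genes)")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(matrix.X.T)  # genes x cells, 10x orientation
    scipy.io.mmwrite(str(d / "matrix.mtx"), X, field="integer")
    feats = pd.DataFrame(
        {"gene_id": matrix.var_names, "gene_symbol": matrix.var["gene_symbol"].values}
    )
    feats.to_csv(d / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(matrix.obs_names).to_csv(
        d / "barcodes.tsv", sep="\t", header=False, index=False
    )
    meta = matrix.obs[_META_COLS].copy()
    meta.insert(0, "barcode", matrix.obs_names)
    meta.to_csv(d / "cells.tsv", sep="\t", index=False)


def read_atlas(directory: str | Path) -> AnnData:
    """Read an atlas directory written by :func:`write_atlas`."""
    d = Path(directory)
    X = sp.csr_matrix(scipy.io.mmread(str(d / "matrix.mtx")).T)
    feats = pd.read_csv(
        d / "features.tsv", sep="\t", header=None, names=["gene_id", "gene_symbol"]
    )
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    meta = pd.read_csv(d / "cells.tsv", sep="\t", dtype=str).set_index("barcode")
    meta = meta.loc[barcodes]
    var = feats.set_index("gene_id")
    adata = AnnData(X=X, obs=meta, var=var)
    adata.uns["layer"] = "raw"
    species = meta["species"].unique()
    if len(species) == 1:
        adata.uns["species"] = str(species[0])
    return adata
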