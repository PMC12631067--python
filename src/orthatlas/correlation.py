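"""Cell-type pseudo-profiles, cross-species Spearman correlation, clustering.

A pseudo-profile is the arithmetic mean of log-normalized expression over
all cells of one (species, cell type).  Profiles are compared with
Spearman's rank correlation over the shared ortholog axis, and the combined
(species, type) set is ordered by average-linkage hierarchical clustering
on the correlation distance d = 1 - rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
import scipy.spatial.distance as ssd
import scipy.stats as st
from anndata import AnnData


@dataclass
class PseudoProfileSet:
    """Mean expression per (species, cell type) over the ortholog axis."""

    profiles: pd.DataFrame  # rows: (species, cell_type) MultiIndex; cols: genes
    n_cells: pd.Series

    @property
    def species(self) -> list[str]:
        return sorted(self.profiles.index.get_level_values("species").unique())


@dataclass
class CorrelationResult:
    rho: pd.DataFrame  # types_A x types_B cross-species block
    rho_full: pd.DataFrame = field(repr=False)  # all (species, type) pairs
    leaf_order: list[tuple[str, str]] | None = None
    linkage_record: np.ndarray | None = field(default=None, repr=False)


def pseudo_profiles(atlas: AnnData, group_by: str = "cell_type") -> PseudoProfileSet:
    """Per-(species, label) mean of the normalized layer."""
    if atlas.uns.get("layer") != "normalized":
        raise ValueError("pseudo_profiles requires a normalized matrix")
    X = sp.csr_matrix(atlas.X)
    keys = list(zip(atlas.obs["species"], atlas.obs[group_by].astype(str)))
    index = sorted(set(keys))
    rows, sizes = [], []
    for key in index:
        mask = np.asarray([k == key for k in keys])
        if not mask.any():
            raise ValueError(f"empty group {key}")
        rows.append(np.asarray(X[mask].mean(axis=0)).ravel())
        sizes.append(int(mask.sum()))
    idx = pd.MultiIndex.from_tuples(index, names=["species", group_by])
    profiles = pd.DataFrame(rows, index=idx, columns=atlas.var_names)
    return PseudoProfileSet(profiles=profiles, n_cells=pd.Series(sizes, index=idx))


def spearman_matrix(p: PseudoProfileSet) -> CorrelationResult:
    """All-pairs Spearman rho between pseudo-profiles.

    Profiles are average-ranked per row, then Pearson-correlated.  A
    zero-variance profile has no defined rank correlation; its entries are
    reported as NaN, never coerced to 0.
    """
    M = p.profiles.to_numpy(dtype=float)
    if M.shape[1] < 2:
        raise ValueError("spearman_matrix needs at least 2 genes")
    ranks = st.rankdata(M, axis=1)
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    rho[sd == 0, :] = np.nan
    rho[:, sd == 0] = np.nan
    np.fill_diagonal(rho, np.where(sd > 0, 1.0, np.nan))
    full = pd.DataFrame(rho, index=p.profiles.index, columns=p.profiles.index)

    species = p.species
    if len(species) == 2:
        a, b = species
        cross = full.loc[a, b]
    else:
        cross = full
    return CorrelationResult(rho=cross, rho_full=full)


def hierarchical_order(c: CorrelationResult) -> CorrelationResult:
    """Average-linkage leaf order of the combined (species, type) set.

    Distance is d = 1 - rho.  Rows enter the agglomeration in lexicographic
    (species, type) order, which makes tie-breaking deterministic.
    """
    full = c.rho_full.sort_index(axis=0).sort_index(axis=1)
    if full.isna().any().any():
        raise ValueError("missing pairwise correlations; cannot cluster")
    d = 1.0 - full.to_numpy()
    np.fill_diagonal(d, 0.0)
    Z = sch.linkage(ssd.squareform(d, checks=False), method="average")
    order = [tuple(full.index[i]) for i in sch.leaves_list(Z)]
    c.leaf_order = order
    c.linkage_record = Z
    return c


def homology_argmax(c: CorrelationResult) -> dict[str, str]:
    """Best-correlated species-B type for each species-A type."""
    return {t: c.rho.loc[t].idxmax() for t in c.rho.index}


def plot_heatmap(c: CorrelationResult, path: str) -> None:
    """Optional clustered heatmap of the full correlation matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if c.leaf_order is None:
        c = hierarchical_order(c)
    full = c.rho_full.loc[c.leaf_order, c.leaf_order]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(full.to_numpy(), cmap="viridis", vmin=-1, vmax=1)
    labels = [f"{s}:{t}" for s, t in full.index]
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
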