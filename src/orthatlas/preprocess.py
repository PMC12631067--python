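"""QC filtering, library-size normalization, and the cluster-uniqueness rule.

Quality control keeps genes detected in at least ``min_cells_per_gene``
cells and then cells expressing at least ``min_genes_per_cell`` of the
retained genes — a single pass, in that order.  Normalization scales each
cell to a fixed total count and applies ln(1 + x).

``unique_cluster_genes`` implements the cluster-annotation rule used for
lineage classification: a gene is unique to a cluster when it is detected
in more than half of that cluster's cells, in at most 10% of the cells of
every other cluster, and its BH-adjusted Wilcoxon p-value (cluster vs rest)
is at most 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scanpy as sc
import scipy.sparse as sp
from anndata import AnnData


@dataclass(frozen=True)
class QCThresholds:
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 50
    normalize_target_sum: float = 10_000.0

    def __post_init__(self):
        if self.min_cells_per_gene < 0 or self.min_genes_per_cell < 0:
            raise ValueError("QC thresholds must be non-negative integers")
        if self.normalize_target_sum <= 0:
            raise ValueError("normalize_target_sum must be positive")


def _require_layer(adata: AnnData, layer: str, op: str) -> None:
    tag = adata.uns.get("layer")
    if tag != layer:
        raise ValueError(f"{op} requires a {layer!r} matrix, got layer={tag!r}")


def filter_cells_genes(
    matrix: AnnData, t: QCThresholds = QCThresholds(), fixpoint: bool = False
) -> AnnData:
    """Gene-then-cell QC filter.

    Genes are kept iff detected (count > 0) in at least ``min_cells_per_gene``
    cells of the *input*; cells are then kept iff they express at least
    ``min_genes_per_cell`` of the retained genes.  With ``fixpoint=True`` the
    two-step pass is iterated to stability.  Removal counts land in
    ``.uns["qc_report"]``.
    """
    _require_layer(matrix, "raw", "filter_cells_genes")
    out = matrix
    genes_removed = 0
    cells_removed = 0
    while True:
        X = sp.csr_matrix(out.X)
        det_cells = (X > 0).sum(axis=0).A1
        keep_genes = det_cells >= t.min_cells_per_gene
        if not keep_genes.any():
            raise ValueError(
                f"no gene is detected in >= {t.min_cells_per_gene} cells "
                "(min_cells_per_gene removed every gene)"
            )
        sub = out[:, keep_genes]
        genes_per_cell = (sp.csr_matrix(sub.X) > 0).sum(axis=1).A1
        keep_cells = genes_per_cell >= t.min_genes_per_cell
        if not keep_cells.any():
            raise ValueError(
                f"no cell expresses >= {t.min_genes_per_cell} retained genes "
                "(min_genes_per_cell removed every cell)"
            )
        genes_removed += int((~keep_genes).sum())
        cells_removed += int((~keep_cells).sum())
        nxt = sub[keep_cells].copy()
        if not fixpoint or (keep_genes.all() and keep_cells.all()):
            out = nxt
            break
        out = nxt
    # disclose whether a further pass would remove more (single-pass
    # filtering is not a fixpoint in general)
    Xf = sp.csr_matrix(out.X)
    stable = bool(((Xf > 0).sum(axis=0).A1 >= t.min_cells_per_gene).all())
    out.uns["layer"] = "raw"
    out.uns["qc_report"] = {
        "genes_removed": genes_removed,
        "cells_removed": cells_removed,
        "fixpoint_requested": bool(fixpoint),
        "is_fixpoint": stable,
    }
    return out


def normalize_log(matrix: AnnData, target_sum: float = 10_000.0) -> AnnData:
    """Scale each cell to ``target_sum`` total counts, then ln(1 + x).

    Raw counts are preserved in ``.layers["counts"]``.
    """
    _require_layer(matrix, "raw", "normalize_log")
    totals = np.asarray(matrix.X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        raise ValueError("cells with zero total count cannot be normalized")
    out = matrix.copy()
    out.layers["counts"] = sp.csr_matrix(out.X).copy()
    out.X = sp.csr_matrix(out.X).astype(np.float64)
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    out.uns["layer"] = "normalized"
    out.uns["normalize_target_sum"] = float(target_sum)
    return out


def regress_out_depth(matrix: AnnData) -> AnnData:
    """Optional per-gene OLS residualization of normalized values on total UMI.

    Mirrors a sequencing-depth regression step; off the default path because
    the downstream comparisons operate on log-normalized values.
    """
    _require_layer(matrix, "normalized", "regress_out_depth")
    out = matrix.copy()
    depth = np.asarray(out.layers["counts"].sum(axis=1)).ravel().astype(float)
    X = np.asarray(sp.csr_matrix(out.X).todense(), dtype=float)
    D = np.column_stack([np.ones_like(depth), depth])
    coef, *_ = np.linalg.lstsq(D, X, rcond=None)
    out.X = X - D @ coef
    out.uns["depth_regressed"] = True
    return out


def unique_cluster_genes(
    matrix: AnnData,
    labels,
    frac_in: float = 0.5,
    frac_out: float = 0.1,
    max_adj_p: float = 0.05,
) -> dict[str, list[str]]:
    """Per-cluster unique genes under the detection + Wilcoxon rule.

    ``labels`` is an ``.obs`` column name or a per-cell label array.
    A gene is unique to cluster k iff its detection fraction in k exceeds
    ``frac_in``, is at most ``frac_out`` in every other cluster, and its
    BH-adjusted Wilcoxon p-value (k vs rest) is at most ``max_adj_p``.
    The returned sets are pairwise disjoint by construction.
    """
    from .diffexpr import wilcoxon_de

    _require_layer(matrix, "normalized", "unique_cluster_genes")
    lab = (
        matrix.obs[labels].to_numpy()
        if isinstance(labels, str)
        else np.asarray(labels)
    )
    if len(lab) != matrix.n_obs:
        raise ValueError("label vector length does not match cell count")
    clusters = sorted(set(map(str, lab)))
    if len(clusters) < 2:
        raise ValueError("unique_cluster_genes needs at least 2 clusters")
    lab = np.asarray([str(x) for x in lab])

    det = {}
    X = sp.csr_matrix(matrix.X)
    for k in clusters:
        det[k] = (X[lab == k] > 0).mean(axis=0).A1
    genes = np.asarray(matrix.var_names)

    out: dict[str, list[str]] = {}
    for k in clusters:
        others = [c for c in clusters if c != k]
        mask = det[k] > frac_in
        for c in others:
            mask &= det[c] <= frac_out
        if not mask.any():
            out[k] = []
            continue
        de = wilcoxon_de(matrix, lab == k, lab != k, min_pct=0.0)
        adj = de.set_index("gene")["adj_p"]
        out[k] = [g for g in genes[mask] if adj.get(g, 1.0) <= max_adj_p]
    return out
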