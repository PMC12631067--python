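"""Ortholog tables, cross-species merging, and UMI accounting.

Two species' post-QC matrices are projected onto a canonical one-to-one
ortholog space: the gene axis keeps exactly those one-to-one pairs whose
members are detected in both species, identified by the canonical ID
"gene_a|gene_b".  UMI accounting reports, per species, the total UMI count
and the fraction assigned to one-to-one orthologous genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

_CLASSES = {"one2one", "one2many", "many2many", "none_a", "none_b"}
_COLUMNS = ["gene_a", "gene_b", "homology_class"]


class OrthologMap:
    """Validated table of (gene_a, gene_b, homology_class) records."""

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in _COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"ortholog table lacks columns: {missing}")
        rec = records[_COLUMNS].copy()
        rec["gene_a"] = rec["gene_a"].fillna("").astype(str)
        rec["gene_b"] = rec["gene_b"].fillna("").astype(str)
        bad = ~rec["homology_class"].isin(_CLASSES)
        if bad.any():
            raise ValueError(
                f"unknown homology_class values: {sorted(set(rec.loc[bad, 'homology_class']))}"
            )
        o2o = rec[rec["homology_class"] == "one2one"]
        if (o2o["gene_a"] == "").any() or (o2o["gene_b"] == "").any():
            raise ValueError("one2one records must name genes on both sides")
        for col in ("gene_a", "gene_b"):
            dup = o2o[col][o2o[col].duplicated()]
            if len(dup):
                raise ValueError(
                    f"duplicate {col} within one2one records: {sorted(set(dup))[:5]}"
                )
        # a gene absent on one side is only legal for the none_* classes
        if ((rec["gene_a"] == "") & (rec["homology_class"] != "none_a")).any():
            raise ValueError("empty gene_a outside class none_a")
        if ((rec["gene_b"] == "") & (rec["homology_class"] != "none_b")).any():
            raise ValueError("empty gene_b outside class none_b")
        self.records = rec.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, OrthologMap) and self.records.equals(other.records)

    def one2one(self) -> pd.DataFrame:
        return self.records[self.records["homology_class"] == "one2one"]

    def a_to_b(self) -> dict[str, str]:
        o = self.one2one()
        return dict(zip(o["gene_a"], o["gene_b"]))

    def b_to_a(self) -> dict[str, str]:
        o = self.one2one()
        return dict(zip(o["gene_b"], o["gene_a"]))

    def side_of(self, gene_ids) -> str:
        """Which column ('a' or 'b') a set of species gene IDs belongs to."""
        ids = set(gene_ids)
        hits_a = len(ids & set(self.records["gene_a"]))
        hits_b = len(ids & set(self.records["gene_b"]))
        if hits_a == hits_b == 0:
            raise ValueError("gene IDs match neither side of the ortholog map")
        return "a" if hits_a >= hits_b else "b"

    def write(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read and validate a TSV with columns gene_a, gene_b, homology_class."""
    records = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return OrthologMap(records)


@dataclass(frozen=True)
class UMIAccounting:
    """Per-species UMI totals and the share on one-to-one orthologs."""

    total_umis: int
    umis_on_one2one: int

    def __post_init__(self):
        if not 0 <= self.umis_on_one2one <= self.total_umis:
            raise ValueError("need 0 <= umis_on_one2one <= total_umis")

    @property
    def pct_kept(self) -> float:
        if self.total_umis == 0:
            return 0.0
        return round(100.0 * self.umis_on_one2one / self.total_umis, 1)

    def summary(self) -> dict:
        return {
            "total_umis": self.total_umis,
            "umis_on_one2one": self.umis_on_one2one,
            "other_umis": self.total_umis - self.umis_on_one2one,
            "pct_kept": self.pct_kept,
        }


def umi_accounting(matrix: AnnData, omap: OrthologMap) -> UMIAccounting:
    """Exact integer UMI accounting of one species' raw matrix."""
    if matrix.uns.get("layer") != "raw":
        raise ValueError("umi_accounting requires raw counts")
    X = sp.csr_matrix(matrix.X)
    total = int(X.sum())
    side = omap.side_of(matrix.var_names)
    o2o_ids = set(omap.one2one()[f"gene_{side}"])
    mask = np.asarray([g in o2o_ids for g in matrix.var_names])
    kept = int(X[:, mask].sum()) if mask.any() else 0
    return UMIAccounting(total_umis=total, umis_on_one2one=kept)


def merge_atlases(a: AnnData, b: AnnData, omap: OrthologMap) -> AnnData:
    """Stack two species' QC-filtered raw matrices in one-to-one ortholog space.

    The merged gene axis keeps the one-to-one pairs whose members are
    detected (count > 0 in at least one cell) in their respective post-QC
    matrices, indexed by the canonical ID "gene_a|gene_b".  Per-species
    UMI accounting (computed on the full post-QC matrices, before the
    ortholog restriction) lands in ``.uns["accounting"]``.
    """
    for m, name in ((a, "a"), (b, "b")):
        if m.uns.get("layer") != "raw":
            raise ValueError(f"matrix {name} must be raw (QC-filtered) counts")
    sp_a = str(a.obs["species"].iloc[0])
    sp_b = str(b.obs["species"].iloc[0])
    if sp_a == sp_b:
        raise ValueError(f"species tag collision: both matrices are {sp_a!r}")

    side_a = omap.side_of(a.var_names)
    side_b = omap.side_of(b.var_names)
    if side_a == side_b:
        raise ValueError("both matrices match the same side of the ortholog map")
    if side_a == "b":  # normalize orientation: matrix a <-> column gene_a
        return _reorder_cells(merge_atlases(b, a, omap), a, b)

    Xa = sp.csc_matrix(a.X)
    Xb = sp.csc_matrix(b.X)
    det_a = {g for g, d in zip(a.var_names, (Xa > 0).sum(axis=0).A1) if d > 0}
    det_b = {g for g, d in zip(b.var_names, (Xb > 0).sum(axis=0).A1) if d > 0}
    o2o = omap.one2one()
    keep = o2o[o2o["gene_a"].isin(det_a) & o2o["gene_b"].isin(det_b)]
    if keep.empty:
        raise ValueError("no one-to-one ortholog pair is expressed in both species")

    ia = pd.Index(a.var_names).get_indexer(keep["gene_a"])
    ib = pd.Index(b.var_names).get_indexer(keep["gene_b"])
    X = sp.vstack([Xa[:, ia], Xb[:, ib]], format="csr")

    obs = pd.concat([a.obs, b.obs], axis=0)
    if not obs.index.is_unique:
        raise ValueError("barcodes collide between the two species")
    var = pd.DataFrame(
        {"gene_a": keep["gene_a"].to_numpy(), "gene_b": keep["gene_b"].to_numpy()},
        index=pd.Index(
            keep["gene_a"].str.cat(keep["gene_b"], sep="|"), name="ortholog_id"
        ),
    )
    merged = AnnData(X=X, obs=obs, var=var)
    merged.uns["layer"] = "raw"
    merged.uns["species_sides"] = {sp_a: "a", sp_b: "b"}
    merged.uns["accounting"] = {
        sp_a: umi_accounting(a, omap).summary(),
        sp_b: umi_accounting(b, omap).summary(),
    }
    return merged


def _reorder_cells(merged: AnnData, first: AnnData, second: AnnData) -> AnnData:
    """Restore caller cell order after an orientation swap."""
    order = list(first.obs_names) + list(second.obs_names)
    out = merged[order].copy()
    out.uns = merged.uns
    return out
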