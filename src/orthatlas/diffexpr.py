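"""Wilcoxon differential expression and the cross-species directional Venn.

Each comparison ranks log-normalized expression of an in-group against an
out-group with the two-sided Mann-Whitney U test (normal approximation with
tie and continuity corrections; exact permutation enumeration when both
groups have at most 8 cells), computes the natural-log
fold change ln((mean(expm1 x_in) + 1) / (mean(expm1 x_out) + 1)), and
adjusts p-values by Benjamini-Hochberg across all tested genes.

The supporting-lineage comparisons contrast each derived supporting type
(Sertoli, pre-granulosa, supporting-like) against the bipotential
pre-supporting progenitor within one species; the two species' thresholded
up/down sets are then partitioned through the one-to-one ortholog map into
species-exclusive and shared (same-direction) cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from anndata import AnnData
from statsmodels.stats.multitest import multipletests

from .ortholog import OrthologMap

_EXACT_MAX_N = 8


@dataclass(frozen=True)
class DEThresholds:
    min_abs_logfc: float = 0.25
    max_adj_p: float = 0.05
    min_pct: float = 0.1

    def __post_init__(self):
        if self.min_abs_logfc < 0 or self.min_pct < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 < self.max_adj_p <= 1:
            raise ValueError("max_adj_p must be in (0, 1]")


def _exact_two_sided_p(ranks: np.ndarray, n1: int) -> float:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Works on pooled midranks, so tied values are handled; the permutation
    distribution of U is symmetric about n1*n2/2 even under ties.
    """
    import itertools

    n = len(ranks)
    offset = n1 * (n1 + 1) / 2.0
    mu = n1 * (n - n1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    dev = abs(u_obs - mu) - 1e-9
    hits = 0
    total = 0
    for comb in itertools.combinations(range(n), n1):
        u = ranks[list(comb)].sum() - offset
        total += 1
        if abs(u - mu) >= dev:
            hits += 1
    return hits / total


def _tie_term(col: np.ndarray) -> float:
    """Sum of t^3 - t over tied groups of one gene's pooled values."""
    _, counts = np.unique(col, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def mannwhitney_u(x_in: np.ndarray, x_out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Mann-Whitney U over genes (columns).

    Returns (U, p) where U is the in-group statistic.  Uses the normal
    approximation with tie correction and a 0.5 continuity correction;
    when both groups have at most 8 cells every gene gets the exact
    permutation-distribution p-value instead.
    """
    x_in = np.atleast_2d(np.asarray(x_in, dtype=float))
    x_out = np.atleast_2d(np.asarray(x_out, dtype=float))
    n1, n2 = x_in.shape[0], x_out.shape[0]
    pooled = np.vstack([x_in, x_out])
    ranks = st.rankdata(pooled, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    ties = np.array([_tie_term(pooled[:, j]) for j in range(pooled.shape[1])])
    var = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u - mu) - 0.5) / np.sqrt(var)
    z = np.where(var > 0, np.maximum(z, 0.0), 0.0)
    p = np.where(var > 0, 2.0 * st.norm.sf(z), 1.0)
    p = np.minimum(p, 1.0)

    if n1 <= _EXACT_MAX_N and n2 <= _EXACT_MAX_N:
        for j in range(pooled.shape[1]):
            p[j] = _exact_two_sided_p(ranks[:, j], n1)
    return u, p


def wilcoxon_de(
    atlas: AnnData,
    in_group,
    out_group,
    t: DEThresholds | None = None,
    min_pct: float | None = None,
) -> pd.DataFrame:
    """Per-gene Wilcoxon DE table for in-group vs out-group cell masks.

    Genes are tested when max(pct_in, pct_out) >= min_pct (detection
    fractions computed on the stored raw counts' zero pattern, identical to
    that of the normalized layer).  Columns: gene, log_fc, p, adj_p,
    pct_in, pct_out, direction.
    """
    if atlas.uns.get("layer") != "normalized":
        raise ValueError("wilcoxon_de requires a normalized matrix")
    if min_pct is None:
        min_pct = (t or DEThresholds()).min_pct
    in_mask = np.asarray(in_group, dtype=bool)
    out_mask = np.asarray(out_group, dtype=bool)
    if in_mask.sum() < 2 or out_mask.sum() < 2:
        raise ValueError("both groups need at least 2 cells")
    if (in_mask & out_mask).any():
        raise ValueError("in_group and out_group overlap")

    X = sp.csr_matrix(atlas.X)
    Xi = np.asarray(X[in_mask].todense(), dtype=float)
    Xo = np.asarray(X[out_mask].todense(), dtype=float)
    pct_in = (Xi > 0).mean(axis=0)
    pct_out = (Xo > 0).mean(axis=0)
    tested = np.maximum(pct_in, pct_out) >= min_pct
    if not tested.any():
        raise ValueError("no gene passes the min_pct detection threshold")

    _, p = mannwhitney_u(Xi[:, tested], Xo[:, tested])
    logfc = np.log(
        (np.expm1(Xi[:, tested]).mean(axis=0) + 1.0)
        / (np.expm1(Xo[:, tested]).mean(axis=0) + 1.0)
    )
    adj_p = multipletests(p, method="fdr_bh")[1]
    genes = np.asarray(atlas.var_names)[tested]
    return pd.DataFrame(
        {
            "gene": genes,
            "log_fc": logfc,
            "p": p,
            "adj_p": adj_p,
            "pct_in": pct_in[tested],
            "pct_out": pct_out[tested],
            "direction": np.where(logfc >= 0, "up", "down"),
        }
    )


def supporting_de(
    atlas: AnnData,
    species: str,
    presupporting_label: str,
    target_label: str,
    t: DEThresholds = DEThresholds(),
) -> tuple[set[str], set[str]]:
    """Thresholded up/down DEG sets for one supporting type of one species.

    Direction is that of the supporting type relative to the pre-supporting
    progenitor: ``up_set`` holds genes with log_fc > min_abs_logfc and
    adj_p < max_adj_p, ``down_set`` those with log_fc < -min_abs_logfc.
    Gene IDs are the species' own IDs when the atlas carries per-species
    gene columns (merged ortholog space), else the atlas var names.
    """
    obs = atlas.obs
    mask_sp = obs["species"].to_numpy() == species
    in_mask = mask_sp & (obs["cell_type"].to_numpy() == target_label)
    out_mask = mask_sp & (obs["cell_type"].to_numpy() == presupporting_label)
    for label, m in ((target_label, in_mask), (presupporting_label, out_mask)):
        if not m.any():
            raise ValueError(f"label {label!r} absent for species {species!r}")
    de = wilcoxon_de(atlas, in_mask, out_mask, t)

    gene_col = f"gene_{atlas.uns['species_sides'][species]}" if "species_sides" in atlas.uns else None
    if gene_col is not None and gene_col in atlas.var.columns:
        id_of = atlas.var[gene_col].to_dict()
        de = de.assign(gene=[id_of[g] for g in de["gene"]])

    sig = de["adj_p"] < t.max_adj_p
    up = set(de.loc[sig & (de["log_fc"] > t.min_abs_logfc), "gene"])
    down = set(de.loc[sig & (de["log_fc"] < -t.min_abs_logfc), "gene"])
    return up, down


@dataclass
class VennPartition:
    """Directional cross-species DEG partition with summary arithmetic."""

    up: dict[str, int]
    down: dict[str, int]
    members: dict[str, dict[str, set[str]]] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        for d in (self.up, self.down):
            d["total"] = d["a_exclusive"] + d["b_exclusive"] + d["shared"]

    @property
    def total_degs(self) -> int:
        return self.up["total"] + self.down["total"]

    @property
    def shared_degs(self) -> int:
        return self.up["shared"] + self.down["shared"]

    @property
    def pct_shared(self) -> float:
        if self.total_degs == 0:
            return 0.0
        return round(100.0 * self.shared_degs / self.total_degs, 1)

    def validate(self) -> None:
        for name, d in (("up", self.up), ("down", self.down)):
            if d["a_exclusive"] + d["b_exclusive"] + d["shared"] != d["total"]:
                raise ValueError(f"inconsistent {name} partition: {d}")

    def summary(self) -> dict:
        return {
            "up": dict(self.up),
            "down": dict(self.down),
            "total_degs": self.total_degs,
            "shared_degs": self.shared_degs,
            "pct_shared": self.pct_shared,
        }


def cross_species_venn(
    a_up: set[str],
    a_down: set[str],
    b_up: set[str],
    b_down: set[str],
    omap: OrthologMap,
) -> VennPartition:
    """Partition two species' directional DEG sets through the ortholog map.

    Per direction, a DEG is shared when the gene and its one-to-one ortholog
    are both in that direction's set; all other members are species
    exclusive, including genes without a one-to-one ortholog.  A gene that
    is discordant in direction between species counts as exclusive in each
    direction.
    """
    if a_up & a_down:
        raise ValueError(f"genes in both up and down of species A: {sorted(a_up & a_down)[:5]}")
    if b_up & b_down:
        raise ValueError(f"genes in both up and down of species B: {sorted(b_up & b_down)[:5]}")
    a2b = omap.a_to_b()
    members: dict[str, dict[str, set[str]]] = {}
    counts = {}
    for direction, sa, sb in (("up", a_up, b_up), ("down", a_down, b_down)):
        shared_a = {g for g in sa if a2b.get(g) in sb}
        shared_b = {a2b[g] for g in shared_a}
        members[direction] = {
            "shared_a": shared_a,
            "shared_b": shared_b,
            "a_exclusive": sa - shared_a,
            "b_exclusive": sb - shared_b,
        }
        counts[direction] = {
            "a_exclusive": len(sa) - len(shared_a),
            "b_exclusive": len(sb) - len(shared_b),
            "shared": len(shared_a),
        }
    part = VennPartition(up=counts["up"], down=counts["down"], members=members)
    part.validate()
    return part
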