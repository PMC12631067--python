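"""Elastic-net one-vs-all cell-identity signatures and cross-species scoring.

For one species and one target cell type, a linear elastic net is fitted to
a balanced training subset (up to 1000 cells per cell type) with a 0/1
response marking the target type.  Features are the genes expressed in more
than 3 training cells, standardized to zero mean and unit variance.  The
signature of the cell type is the set of genes with strictly positive
weight, and the fitted model scores any cell — of either species, through
the one-to-one ortholog map — as intercept + standardized expression dot
weights.

The penalized objective is ||y - Xw - b||^2 / (2n) + lam * (alpha*|w|_1 +
(1-alpha)*|w|_2^2 / 2) with mixing alpha = l1_ratio, solved by cyclic
coordinate descent (scikit-learn's ElasticNet).  lam defaults to a 5-fold
cross-validated grid with the one-standard-error rule, which favours the
sparsest model whose CV error is within one SE of the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .ortholog import OrthologMap

_MIN_TRAIN_CELLS_PER_GENE = 3  # features: genes expressed in > 3 cells


@dataclass
class SignatureModel:
    species: str
    cell_type: str
    genes: list[str]
    weights: np.ndarray
    intercept: float
    mean: np.ndarray
    sd: np.ndarray
    l1_ratio: float
    penalty: float
    train_seed: int | None = None
    train_cell_ids: list[str] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "cell_type": self.cell_type,
            "genes": list(self.genes),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "l1_ratio": self.l1_ratio,
            "penalty": self.penalty,
            "train_seed": self.train_seed,
            "train_cell_ids": list(self.train_cell_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        d = dict(d)
        for k in ("weights", "mean", "sd"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def balanced_sample(labels, n_per_type: int = 1000, seed: int = 0) -> np.ndarray:
    """Indices of up to ``n_per_type`` cells per label, sampled without
    replacement; deterministic given the seed."""
    lab = np.asarray(labels)
    if lab.size == 0:
        raise ValueError("labels are empty")
    rng = np.random.default_rng(seed)
    picked = []
    for t in sorted(set(map(str, lab))):
        idx = np.flatnonzero(lab.astype(str) == t)
        if len(idx) > n_per_type:
            idx = np.sort(rng.choice(idx, size=n_per_type, replace=False))
        picked.append(idx)
    return np.concatenate(picked)


def _cv_penalty(X, y, l1_ratio, seed, n_alphas=12):
    # grid spans two decades below the smallest penalty that zeroes every
    # weight; the one-SE rule never selects the dense low-penalty regime,
    # so the grid need not extend into it
    cv = KFold(n_splits=5, shuffle=True, random_state=seed)
    model = ElasticNetCV(
        l1_ratio=l1_ratio, alphas=n_alphas, eps=1e-2, cv=cv, max_iter=3000, tol=1e-5
    )
    model.fit(X, y)
    mse = model.mse_path_.mean(axis=1)
    se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
    i_min = int(np.argmin(mse))
    cutoff = mse[i_min] + se[i_min]
    # alphas_ are descending; the first index under the cutoff is the
    # largest (sparsest) penalty within one SE of the CV minimum
    i_1se = int(np.flatnonzero(mse <= cutoff)[0])
    return float(model.alphas_[i_1se])


def fit_signature(
    matrix: AnnData,
    target_type: str,
    l1_ratio: float = 0.5,
    penalty: float | str = "cv",
    seed: int = 0,
) -> SignatureModel:
    """Fit the one-vs-all elastic net for one cell type.

    ``matrix`` is the (balanced) normalized training subset of one species;
    ``penalty`` is either a fixed lam or "cv" for the 5-fold
    one-standard-error grid choice.
    """
    if matrix.uns.get("layer") != "normalized":
        raise ValueError("fit_signature requires a normalized matrix")
    y = (matrix.obs["cell_type"].astype(str) == target_type).to_numpy(float)
    if y.all() or not y.any():
        raise ValueError(f"training set has a single class for {target_type!r}")

    X = np.asarray(sp.csr_matrix(matrix.X).todense(), dtype=float)
    expressed = (X > 0).sum(axis=0) > _MIN_TRAIN_CELLS_PER_GENE
    sd = X.std(axis=0)
    keep = expressed & (sd > 0)
    genes = list(np.asarray(matrix.var_names)[keep])
    mean = X[:, keep].mean(axis=0)
    sd = X[:, keep].std(axis=0)
    Z = (X[:, keep] - mean) / sd

    if penalty == "cv":
        lam = _cv_penalty(Z, y, l1_ratio, seed)
    else:
        lam = float(penalty)
    enet = ElasticNet(alpha=lam, l1_ratio=l1_ratio, max_iter=5000, tol=1e-7)
    enet.fit(Z, y)

    species = str(matrix.obs["species"].iloc[0])
    return SignatureModel(
        species=species,
        cell_type=target_type,
        genes=genes,
        weights=np.asarray(enet.coef_, dtype=float),
        intercept=float(enet.intercept_),
        mean=mean,
        sd=sd,
        l1_ratio=l1_ratio,
        penalty=lam,
        train_seed=seed,
        train_cell_ids=list(matrix.obs_names),
    )


def extract_signature(model: SignatureModel) -> list[str]:
    """Genes with strictly positive weight, by descending weight."""
    pos = model.weights > 0
    order = np.argsort(-model.weights[pos])
    return [np.asarray(model.genes)[pos][i] for i in order]


def score_cells(model: SignatureModel, atlas: AnnData) -> pd.DataFrame:
    """Score every cell of a (merged) atlas with a fitted identity model.

    Model genes are matched to atlas columns directly, or through the
    per-species gene columns of a merged ortholog-space atlas.  Genes
    absent from the atlas contribute their standardized training mean
    (0); the number of missing genes is reported, and more than 50%
    missing is an error.
    """
    if atlas.uns.get("layer") != "normalized":
        raise ValueError("score_cells requires a normalized matrix")
    sides = atlas.uns.get("species_sides", {})
    pos_of = {g: i for i, g in enumerate(atlas.var_names)}
    if model.species in sides and not any(g in pos_of for g in model.genes):
        # model trained in species gene space; route through the ortholog side
        col = atlas.var[f"gene_{sides[model.species]}"]
        pos_of = {g: i for i, g in enumerate(col)}

    cols = [pos_of.get(g, -1) for g in model.genes]
    present = np.asarray(cols) >= 0
    n_missing = int((~present).sum())
    if n_missing > 0.5 * len(model.genes):
        raise ValueError(
            f"{n_missing}/{len(model.genes)} model genes missing from the atlas"
        )
    X = np.asarray(sp.csr_matrix(atlas.X).todense(), dtype=float)
    Z = np.zeros((atlas.n_obs, len(model.genes)))
    idx = np.asarray(cols)[present]
    Z[:, present] = (X[:, idx] - model.mean[present]) / model.sd[present]
    scores = model.intercept + Z @ model.weights
    out = atlas.obs[["species", "cell_type"]].copy()
    out["score"] = scores
    out.attrs["n_missing_genes"] = n_missing
    return out


@dataclass(frozen=True)
class SignatureOverlap:
    """Cross-species composition of one cell type's signatures."""

    shared: int
    a_exclusive: int
    b_exclusive: int

    @property
    def species_a_total(self) -> int:
        return self.a_exclusive + self.shared

    @property
    def species_b_total(self) -> int:
        return self.b_exclusive + self.shared

    def summary(self) -> dict:
        return {
            "shared": self.shared,
            "a_exclusive": self.a_exclusive,
            "b_exclusive": self.b_exclusive,
            "species_a_total": self.species_a_total,
            "species_b_total": self.species_b_total,
        }


def signature_overlap(sig_a, sig_b, omap: OrthologMap) -> SignatureOverlap:
    """Partition two species' signature gene lists through the ortholog map."""
    sa, sb = set(sig_a), set(sig_b)
    a2b = omap.a_to_b()
    shared = {g for g in sa if a2b.get(g) in sb}
    shared_b = {a2b[g] for g in shared}
    return SignatureOverlap(
        shared=len(shared),
        a_exclusive=len(sa) - len(shared),
        b_exclusive=len(sb) - len(shared_b),
    )
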