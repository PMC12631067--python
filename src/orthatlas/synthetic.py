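"""Dual-species synthetic single-cell atlas with planted ground truth.

Generates UMI count matrices for two species ("human", "mouse") whose cell
types are homologous by construction: homologous types share identical
baseline expression programs in ortholog space, and divergence is planted
explicitly as conserved (shared through the ortholog map) and
species-specific marker genes.  Counts follow a negative-binomial model with
a per-cell log-normal library-size multiplier, the standard description of
droplet scRNA-seq UMI data.

The generator emulates the structure of a gonadal sex-determination atlas:
one bipotential "pre_supporting" progenitor plus three derived supporting
types (sertoli, pre_granulosa, supporting_like), alongside generic somatic
populations.  Differential-expression ground truth between the progenitor
and each supporting type follows directly from the planted markers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

SPECIES_A = "human"
SPECIES_B = "mouse"
GENE_PREFIX = {SPECIES_A: "hsa", SPECIES_B: "mmu"}

PRE_SUPPORTING = "pre_supporting"
SUPPORTING_TYPES = ("sertoli", "pre_granulosa", "supporting_like")
_EXTRA_TYPES = (
    "germ",
    "endothelial",
    "immune",
    "leydig",
    "steroidogenic_progenitor",
    "coelomic_epithelial",
    "perivascular",
    "erythrocyte",
    "mesonephros",
)

_STAGES = {
    SPECIES_A: ("PCW6", "PCW7", "PCW8", "PCW9", "PCW10", "PCW11-12"),
    SPECIES_B: ("E10.5", "E11.5", "E12.5", "E13.5", "E16.5"),
}

# Markers are drawn from genes above this baseline-weight quantile so the
# planted programs are detectable at realistic depth: a cell-type marker is,
# by definition, a gene the type expresses.
_MARKER_BASELINE_QUANTILE = 0.25


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the dual-species simulation.

    Defaults describe a desk-scale atlas: 6 cell types x 300 cells per type
    per species over 2,000 one-to-one ortholog pairs, with a natural-log
    marker effect of 1.2 and moderate overdispersion (phi=2) typical of
    droplet UMI counts.
    """

    n_types: int = 6
    cells_per_type_per_species: int = 300
    n_ortholog_pairs: int = 2000
    frac_non_one2one: float = 0.2
    conserved_markers_per_type: int = 15
    specific_markers_per_type_per_species: int = 10
    marker_log_effect: float = 1.2
    libsize_lognormal_params: tuple[float, float] = (0.0, 0.35)
    nb_dispersion: float = 2.0
    mean_depth: float = 5000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_types < 4:
            raise ValueError(
                "n_types must be >= 4 (pre-supporting progenitor plus three "
                "derived supporting types)"
            )
        for name in (
            "cells_per_type_per_species",
            "n_ortholog_pairs",
            "conserved_markers_per_type",
            "specific_markers_per_type_per_species",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.frac_non_one2one < 1.0:
            raise ValueError("frac_non_one2one must be in [0, 1)")
        if self.marker_log_effect < 0:
            raise ValueError("marker_log_effect must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        n_genes = self.n_genes_per_species
        demand = self.n_types * (
            self.conserved_markers_per_type
            + self.specific_markers_per_type_per_species
        )
        # Markers come from the upper (1 - q) baseline quantile of each
        # species' genes; conserved markers additionally need one2one pairs.
        eligible = int((1.0 - _MARKER_BASELINE_QUANTILE) * self.n_ortholog_pairs)
        if demand > eligible:
            raise ValueError(
                f"marker demand ({demand} genes) exceeds the eligible gene "
                f"pool ({eligible} of {n_genes} genes)"
            )

    @property
    def n_unpaired_per_species(self) -> int:
        f = self.frac_non_one2one
        return int(round(self.n_ortholog_pairs * f / (1.0 - f)))

    @property
    def n_genes_per_species(self) -> int:
        return self.n_ortholog_pairs + self.n_unpaired_per_species

    def cell_type_names(self) -> list[str]:
        names = [PRE_SUPPORTING, *SUPPORTING_TYPES]
        extra = self.n_types - len(names)
        if extra > len(_EXTRA_TYPES):
            names += [f"somatic_{i}" for i in range(extra)]
        else:
            names += list(_EXTRA_TYPES[:extra])
        return names[: self.n_types]


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated dual atlas.

    homology maps each species-A cell type to its species-B counterpart.
    markers[species][cell_type] holds two disjoint gene-ID sets,
    "conserved" and "specific".  de_truth[species][supporting_type] holds
    the planted "up" and "down" gene sets of the supporting type relative
    to the pre-supporting progenitor.
    """

    homology: dict[str, str]
    markers: dict[str, dict[str, dict[str, set[str]]]]
    de_truth: dict[str, dict[str, dict[str, set[str]]]]
    config: SimConfig = field(repr=False)

    def conserved_de(self, supporting_type: str, direction: str) -> set[str]:
        """Planted conserved DE genes (species-A IDs) for one comparison."""
        a = self.de_truth[SPECIES_A][supporting_type][direction]
        conserved_a = (
            self.markers[SPECIES_A][supporting_type]["conserved"]
            | self.markers[SPECIES_A][PRE_SUPPORTING]["conserved"]
        )
        return a & conserved_a

    def to_json(self, path: str | Path) -> None:
        def _sets(d):
            if isinstance(d, dict):
                return {k: _sets(v) for k, v in d.items()}
            if isinstance(d, (set, frozenset)):
                return sorted(d)
            return d

        payload = {
            "homology": self.homology,
            "markers": _sets(self.markers),
            "de_truth": _sets(self.de_truth),
            "config": dataclasses.asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())

        def _sets(d):
            if isinstance(d, dict):
                return {k: _sets(v) for k, v in d.items()}
            if isinstance(d, list):
                return set(d)
            return d

        cfg = raw["config"]
        cfg["libsize_lognormal_params"] = tuple(cfg["libsize_lognormal_params"])
        return cls(
            homology=raw["homology"],
            markers=_sets(raw["markers"]),
            de_truth=_sets(raw["de_truth"]),
            config=SimConfig(**cfg),
        )


def _gene_ids(species: str, n: int) -> list[str]:
    pre = GENE_PREFIX[species]
    width = max(4, len(str(n)))
    return [f"{pre}:G{i + 1:0{width}d}" for i in range(n)]


def _assign_markers(
    cfg: SimConfig, rng: np.random.Generator, baseline_pairs: np.ndarray,
    baseline_unpaired: dict[str, np.ndarray],
) -> dict[str, dict[str, dict[str, np.ndarray]]]:
    """Choose marker gene *indices* per (species, type), disjoint within species.

    Conserved markers are ortholog-pair indices (shared by construction);
    specific markers are per-species gene indices drawn from paired and
    unpaired genes alike.  Eligibility restricts to genes above the baseline
    quantile so markers sit on an expressed background.
    """
    types = cfg.cell_type_names()
    thresh = np.quantile(baseline_pairs, _MARKER_BASELINE_QUANTILE)
    eligible_pairs = np.flatnonzero(baseline_pairs >= thresh)
    order = rng.permutation(eligible_pairs)
    k = cfg.conserved_markers_per_type
    conserved = {t: np.sort(order[i * k : (i + 1) * k]) for i, t in enumerate(types)}
    used_pairs = set(order[: len(types) * k].tolist())

    out: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for species in (SPECIES_A, SPECIES_B):
        unp = baseline_unpaired[species]
        t_unp = np.quantile(unp, _MARKER_BASELINE_QUANTILE) if unp.size else np.inf
        elig = np.concatenate(
            [
                np.flatnonzero(baseline_pairs >= thresh),
                cfg.n_ortholog_pairs + np.flatnonzero(unp >= t_unp),
            ]
        )
        elig = np.array([g for g in elig if g not in used_pairs], dtype=int)
        order_s = rng.permutation(elig)
        m = cfg.specific_markers_per_type_per_species
        out[species] = {}
        for i, t in enumerate(types):
            chosen = np.sort(order_s[i * m : (i + 1) * m])
            out[species][t] = {"conserved": conserved[t], "specific": chosen}
        # keep specific markers ortholog-disjoint across species so that
        # "specific" never aliases an unplanted conserved program
        used_pairs |= {g for g in order_s[: len(types) * m] if g < cfg.n_ortholog_pairs}
    return out


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with variance m + m^2/phi via gamma-Poisson mixing."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def _species_matrix(
    cfg: SimConfig,
    species: str,
    probs: dict[str, np.ndarray],
    gene_ids: list[str],
    rng_lib: np.random.Generator,
    rng_counts: np.random.Generator,
) -> AnnData:
    types = cfg.cell_type_names()
    n_cells = cfg.cells_per_type_per_species * len(types)
    mu, sigma = cfg.libsize_lognormal_params
    mult = rng_lib.lognormal(mean=mu, sigma=sigma, size=n_cells)
    libsize = cfg.mean_depth * mult / np.exp(mu + sigma**2 / 2.0)

    blocks = []
    cell_types = []
    for i, t in enumerate(types):
        lo = i * cfg.cells_per_type_per_species
        hi = lo + cfg.cells_per_type_per_species
        mean = libsize[lo:hi, None] * probs[t][None, :]
        blocks.append(sp.csr_matrix(_nb_counts(rng_counts, mean, cfg.nb_dispersion)))
        cell_types += [t] * cfg.cells_per_type_per_species
    X = sp.vstack(blocks, format="csr")
    X.data = X.data.astype(np.int64)

    stages = _STAGES[species]
    obs = pd.DataFrame(
        {
            "species": species,
            "sex": [("XX", "XY")[i % 2] for i in range(n_cells)],
            "stage": [stages[i % len(stages)] for i in range(n_cells)],
            "cell_type": cell_types,
        },
        index=[f"{GENE_PREFIX[species]}-cell-{i + 1:05d}" for i in range(n_cells)],
    )
    obs.index.name = "barcode"
    var = pd.DataFrame(
        {"gene_symbol": [g.split(":", 1)[1] for g in gene_ids]},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    adata = AnnData(X=X, obs=obs, var=var)
    adata.uns["layer"] = "raw"
    adata.uns["species"] = species
    return adata


def expression_programs(cfg: SimConfig):
    """Deterministic per-type gene-probability vectors and marker indices.

    Returns ``(probs, markers_idx, gene_ids)`` where
    ``probs[species][cell_type]`` sums to 1 over that species' genes:
    shared baseline log-weights in ortholog space plus the marker effect on
    that type's marker genes, renormalized.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(6)
    rng_base = np.random.default_rng(children[0])
    rng_mark = np.random.default_rng(children[1])

    n_pairs = cfg.n_ortholog_pairs
    n_unp = cfg.n_unpaired_per_species
    # Baseline log-weights: shared across species for ortholog pairs (the
    # conservation null), independent for unpaired genes.
    base_pairs = rng_base.normal(0.0, 1.0, size=n_pairs)
    base_unpaired = {
        SPECIES_A: rng_base.normal(0.0, 1.0, size=n_unp),
        SPECIES_B: rng_base.normal(0.0, 1.0, size=n_unp),
    }
    markers_idx = _assign_markers(cfg, rng_mark, base_pairs, base_unpaired)
    gene_ids = {s: _gene_ids(s, cfg.n_genes_per_species) for s in (SPECIES_A, SPECIES_B)}

    probs: dict[str, dict[str, np.ndarray]] = {}
    for species in (SPECIES_A, SPECIES_B):
        logw0 = np.concatenate([base_pairs, base_unpaired[species]])
        probs[species] = {}
        for t in cfg.cell_type_names():
            logw = logw0.copy()
            m = markers_idx[species][t]
            boost = np.concatenate([m["conserved"], m["specific"]])
            logw[boost] += cfg.marker_log_effect
            w = np.exp(logw)
            probs[species][t] = w / w.sum()
    return probs, markers_idx, gene_ids


def simulate_dual_atlas(config: SimConfig | None = None):
    """Simulate a two-species atlas with planted homology and markers.

    Returns ``(adata_a, adata_b, ortholog_map, truth)`` where the matrices
    are raw-count :class:`~anndata.AnnData` objects (cells x genes), the
    ortholog map covers exactly the configured one-to-one pairs plus the
    unpaired remainder of each species, and ``truth`` records every planted
    structure.  Fully reproducible from ``config.seed``.
    """
    from .ortholog import OrthologMap

    cfg = config or SimConfig()
    cfg.validate()

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(6)
    rng_lib_a, rng_lib_b, rng_cnt_a, rng_cnt_b = (
        np.random.default_rng(s) for s in children[2:]
    )
    probs, markers_idx, gene_ids = expression_programs(cfg)
    n_pairs = cfg.n_ortholog_pairs
    n_unp = cfg.n_unpaired_per_species
    types = cfg.cell_type_names()

    adata_a = _species_matrix(cfg, SPECIES_A, probs[SPECIES_A], gene_ids[SPECIES_A],
                              rng_lib_a, rng_cnt_a)
    adata_b = _species_matrix(cfg, SPECIES_B, probs[SPECIES_B], gene_ids[SPECIES_B],
                              rng_lib_b, rng_cnt_b)

    records = pd.DataFrame(
        {
            "gene_a": gene_ids[SPECIES_A][:n_pairs]
            + gene_ids[SPECIES_A][n_pairs:]
            + [""] * n_unp,
            "gene_b": gene_ids[SPECIES_B][:n_pairs]
            + [""] * n_unp
            + gene_ids[SPECIES_B][n_pairs:],
            "homology_class": ["one2one"] * n_pairs
            + ["none_b"] * n_unp
            + ["none_a"] * n_unp,
        }
    )
    omap = OrthologMap(records)

    markers: dict[str, dict[str, dict[str, set[str]]]] = {}
    for species in (SPECIES_A, SPECIES_B):
        ids = gene_ids[species]
        markers[species] = {}
        for t in types:
            m = markers_idx[species][t]
            markers[species][t] = {
                "conserved": {ids[i] for i in m["conserved"]},
                "specific": {ids[i] for i in m["specific"]},
            }
    de_truth: dict[str, dict[str, dict[str, set[str]]]] = {}
    for species in (SPECIES_A, SPECIES_B):
        de_truth[species] = {}
        for t in (x for x in SUPPORTING_TYPES if x in types):
            up = markers[species][t]["conserved"] | markers[species][t]["specific"]
            down = (
                markers[species][PRE_SUPPORTING]["conserved"]
                | markers[species][PRE_SUPPORTING]["specific"]
            )
            de_truth[species][t] = {"up": up, "down": down}
    if cfg.marker_log_effect == 0.0:
        de_truth = {
            s: {t: {"up": set(), "down": set()} for t in de_truth[s]} for s in de_truth
        }

    truth = SyntheticTruth(
        homology={t: t for t in types},
        markers=markers,
        de_truth=de_truth,
        config=cfg,
    )
    return adata_a, adata_b, omap, truth


def write_atlas(matrix: AnnData, directory: str | Path) -> None:
    """Write one species' matrix as an MTX triplet plus cell metadata.

    Emits ``matrix.mtx`` (genes x cells, integer MatrixMarket),
    ``features.tsv`` (gene_id, gene_symbol), ``barcodes.tsv`` and
    ``cells.tsv`` (barcode, species, sex, stage, cell_type).  Round-trips
    losslessly through :func:`orthatlas.io.read_atlas`.
    """
    from .io import write_atlas as _write

    _write(matrix, directory)
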