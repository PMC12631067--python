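"""Truth-recovery studies on the synthetic dual atlas.

Runs the full comparison pipeline over replicate simulations and measures
how well each stage recovers the planted ground truth: homologous-type
assignment by correlation argmax, conserved differentially expressed genes
landing in the shared Venn cell, elastic-net signature precision/recall
against planted markers, and cross-species score transfer.  A null variant
(marker effect 0) measures the false-shared and false-discovery rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .correlation import homology_argmax, pseudo_profiles, spearman_matrix
from .diffexpr import DEThresholds, cross_species_venn, supporting_de, wilcoxon_de
from .ortholog import merge_atlases
from .preprocess import filter_cells_genes, normalize_log
from .signatures import balanced_sample, extract_signature, fit_signature, score_cells
from .synthetic import PRE_SUPPORTING, SUPPORTING_TYPES, SimConfig, simulate_dual_atlas


@dataclass
class RecoveryMetrics:
    """Pooled truth-recovery results over replicate simulations."""

    n_seeds: int
    argmax_correct: int = 0
    argmax_total: int = 0
    conserved_recovered: int = 0
    conserved_planted: int = 0
    precisions: list[float] = field(default_factory=list)
    recalls: list[float] = field(default_factory=list)
    transfer_top1: list[bool] = field(default_factory=list)

    @property
    def argmax_recovery(self) -> float:
        return self.argmax_correct / self.argmax_total

    @property
    def conserved_recall(self) -> float:
        return self.conserved_recovered / self.conserved_planted

    @property
    def transfer_top1_rate(self) -> float:
        return float(np.mean(self.transfer_top1))

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precisions))

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.recalls))


@dataclass
class NullMetrics:
    """False-positive behaviour when no effect is planted."""

    n_seeds: int
    shared_degs: int = 0
    total_degs: int = 0
    ortholog_tests: int = 0
    gene_tests: int = 0
    rejections: int = 0

    @property
    def false_shared_rate(self) -> float:
        return self.shared_degs / self.ortholog_tests

    @property
    def rejection_rate(self) -> float:
        return self.rejections / self.gene_tests


def _prepare(cfg: SimConfig):
    a, b, omap, truth = simulate_dual_atlas(cfg)
    a, b = filter_cells_genes(a), filter_cells_genes(b)
    merged = normalize_log(merge_atlases(a, b, omap))
    return merged, omap, truth


def recovery_study(
    seeds,
    config: SimConfig | None = None,
    thresholds: DEThresholds = DEThresholds(),
    with_signatures: bool = True,
    signature_type: str = "sertoli",
) -> RecoveryMetrics:
    """Measure truth recovery of every pipeline stage across seeds.

    Per seed: (i) correlation argmax vs the planted homology over all cell
    types; (ii) the fraction of planted conserved DE genes (restricted to
    the merged ortholog space) recovered into the shared Venn cell, pooled
    over the three supporting-lineage comparisons; (iii) optionally, for
    ``signature_type`` in both species, signature precision/recall against
    planted markers and whether the cross-species mean score ranks the
    homologous type first.
    """
    base = config or SimConfig()
    seeds = list(seeds)
    out = RecoveryMetrics(n_seeds=len(seeds))
    for seed in seeds:
        merged, omap, truth = _prepare(dataclasses.replace(base, seed=seed))
        species = sorted(truth.markers)
        side = merged.uns["species_sides"]
        gene_of = {sp: set(merged.var[f"gene_{side[sp]}"]) for sp in species}

        argmax = homology_argmax(spearman_matrix(pseudo_profiles(merged)))
        out.argmax_correct += sum(argmax[t] == truth.homology[t] for t in argmax)
        out.argmax_total += len(argmax)

        sp_a = next(sp for sp in species if side[sp] == "a")
        sp_b = next(sp for sp in species if side[sp] == "b")
        for target in (t for t in SUPPORTING_TYPES if t in truth.homology):
            a_up, a_down = supporting_de(merged, sp_a, PRE_SUPPORTING, target, thresholds)
            b_up, b_down = supporting_de(merged, sp_b, PRE_SUPPORTING, target, thresholds)
            venn = cross_species_venn(a_up, a_down, b_up, b_down, omap)
            for direction in ("up", "down"):
                planted = truth.conserved_de(target, direction) & gene_of[sp_a]
                got = venn.members[direction]["shared_a"]
                out.conserved_recovered += len(got & planted)
                out.conserved_planted += len(planted)

        if with_signatures:
            for sp in species:
                sub = merged[merged.obs["species"].to_numpy() == sp].copy()
                sub.uns = dict(merged.uns)
                idx = balanced_sample(sub.obs["cell_type"], 1000, seed=seed)
                train = sub[idx].copy()
                train.uns = dict(sub.uns)
                model = fit_signature(train, signature_type, penalty="cv", seed=seed)
                sig = extract_signature(model)
                sig_native = set(merged.var.loc[sig, f"gene_{side[sp]}"])
                m = truth.markers[sp][signature_type]
                planted = (m["conserved"] | m["specific"]) & gene_of[sp]
                tp = len(sig_native & planted)
                out.precisions.append(tp / len(sig_native) if sig_native else 0.0)
                out.recalls.append(tp / len(planted))

                other = next(s for s in species if s != sp)
                scores = score_cells(model, merged)
                other_scores = scores[scores["species"] == other]
                best = other_scores.groupby("cell_type", observed=True)["score"].mean().idxmax()
                out.transfer_top1.append(best == truth.homology[signature_type])
    return out


def null_study(
    seeds,
    config: SimConfig | None = None,
    thresholds: DEThresholds = DEThresholds(),
) -> NullMetrics:
    """False-positive rates with marker effect 0 (no planted divergence)."""
    base = dataclasses.replace(config or SimConfig(), marker_log_effect=0.0)
    seeds = list(seeds)
    out = NullMetrics(n_seeds=len(seeds))
    for seed in seeds:
        merged, omap, truth = _prepare(dataclasses.replace(base, seed=seed))
        species = sorted(truth.markers)
        side = merged.uns["species_sides"]
        sp_a = next(sp for sp in species if side[sp] == "a")
        sp_b = next(sp for sp in species if side[sp] == "b")
        obs = merged.obs
        for target in (t for t in SUPPORTING_TYPES if t in truth.homology):
            a_up, a_down = supporting_de(merged, sp_a, PRE_SUPPORTING, target, thresholds)
            b_up, b_down = supporting_de(merged, sp_b, PRE_SUPPORTING, target, thresholds)
            venn = cross_species_venn(a_up, a_down, b_up, b_down, omap)
            out.shared_degs += venn.shared_degs
            out.total_degs += venn.total_degs
            out.ortholog_tests += merged.n_vars
            # per-gene Wilcoxon rejections for the BH type-I check
            for sp in (sp_a, sp_b):
                mask_sp = obs["species"].to_numpy() == sp
                lab = obs["cell_type"].to_numpy()
                de = wilcoxon_de(
                    merged,
                    mask_sp & (lab == target),
                    mask_sp & (lab == PRE_SUPPORTING),
                    thresholds,
                )
                out.gene_tests += len(de)
                out.rejections += int((de["adj_p"] < 0.05).sum())
    return out
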