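"""End-to-end orchestration: simulate/load -> QC -> merge -> correlate ->
DE + Venn -> signatures -> enrichment -> run report.

Every stage writes its tabular outputs under the run directory and
contributes a summary entry to the final ``report.json``; Venn arithmetic
is re-validated at report time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as atlas_io
from . import synthetic
from .correlation import homology_argmax, hierarchical_order, pseudo_profiles, spearman_matrix
from .diffexpr import DEThresholds, cross_species_venn, supporting_de
from .enrichment import hypergeom_ora, read_gmt
from .ortholog import read_ortholog_map
from .preprocess import QCThresholds, filter_cells_genes, normalize_log
from .signatures import (
    balanced_sample,
    extract_signature,
    fit_signature,
    score_cells,
    signature_overlap,
)
from .synthetic import PRE_SUPPORTING, SUPPORTING_TYPES, SimConfig

log = logging.getLogger("orthatlas")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    outdir: str = "orthatlas_run"
    seed: int = 0
    # either both atlas dirs + ortholog map, or a synthetic simulation
    atlas_a: str | None = None
    atlas_b: str | None = None
    ortholog_map: str | None = None
    gmt: str | None = None
    synthetic: SimConfig = field(default_factory=SimConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    de: DEThresholds = field(default_factory=DEThresholds)
    presupporting_label: str = PRE_SUPPORTING
    supporting_labels: tuple[str, ...] = SUPPORTING_TYPES
    signature_targets: tuple[str, ...] = SUPPORTING_TYPES
    n_train_per_type: int = 1000
    l1_ratio: float = 0.5
    penalty: float | str = "cv"
    run_enrichment: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("synthetic", SimConfig), ("qc", QCThresholds), ("de", DEThresholds)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        paths = [self.atlas_a, self.atlas_b, self.ortholog_map]
        if any(p is not None for p in paths):
            if not all(p is not None for p in paths):
                raise ConfigError(
                    "atlas_a, atlas_b and ortholog_map must be given together"
                )
            for p in paths + ([self.gmt] if self.gmt else []):
                if p and not Path(p).exists():
                    raise ConfigError(f"input path does not exist: {p}")
        elif self.gmt and not Path(self.gmt).exists():
            raise ConfigError(f"input path does not exist: {self.gmt}")
        self.synthetic.validate()


def _echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _echo(config), "stages": {}}
    from . import __version__

    report["version"] = __version__

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)

        def done(summary):
            report["stages"][name] = {
                "summary": summary,
                "seconds": round(time.perf_counter() - t0, 3),
            }
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)

        return done

    # --- simulate or load -------------------------------------------------
    done = stage("input")
    if config.atlas_a:
        a = atlas_io.read_atlas(config.atlas_a)
        b = atlas_io.read_atlas(config.atlas_b)
        omap = read_ortholog_map(config.ortholog_map)
        truth = None
        done({"source": "files", "cells_a": a.n_obs, "cells_b": b.n_obs})
    else:
        sim = dataclasses.replace(config.synthetic, seed=config.seed)
        a, b, omap, truth = synthetic.simulate_dual_atlas(sim)
        truth.to_json(outdir / "truth.json")
        done({"source": "synthetic", "cells_a": a.n_obs, "cells_b": b.n_obs,
              "genes_per_species": sim.n_genes_per_species})

    # --- qc ---------------------------------------------------------------
    done = stage("qc")
    a = filter_cells_genes(a, config.qc)
    b = filter_cells_genes(b, config.qc)
    done({sp: m.uns["qc_report"] for sp, m in
          ((str(a.obs["species"].iloc[0]), a), (str(b.obs["species"].iloc[0]), b))})

    # --- merge ------------------------------------------------------------
    done = stage("merge")
    from .ortholog import merge_atlases

    merged = merge_atlases(a, b, omap)
    accounting = merged.uns["accounting"]
    (outdir / "accounting.json").write_text(json.dumps(accounting, indent=1))
    merged = normalize_log(merged, config.qc.normalize_target_sum)
    done({"n_cells": merged.n_obs, "n_orthologs": merged.n_vars,
          "accounting": accounting})

    # --- correlate --------------------------------------------------------
    done = stage("correlate")
    prof = pseudo_profiles(merged)
    corr = hierarchical_order(spearman_matrix(prof))
    corr.rho.to_csv(outdir / "correlation.tsv", sep="\t")
    argmax = homology_argmax(corr)
    (outdir / "linkage.json").write_text(json.dumps(
        {"leaf_order": [list(x) for x in corr.leaf_order],
         "linkage": corr.linkage_record.tolist()}, indent=1))
    done({"argmax": argmax, "leaf_order": [list(x) for x in corr.leaf_order]})

    # --- de + venn --------------------------------------------------------
    done = stage("de_venn")
    species = sorted(set(merged.obs["species"]))
    side = merged.uns["species_sides"]
    # orient so "species a" is the one on the gene_a side of the map
    sp_first = species[0] if side[species[0]] == "a" else species[1]
    sp_second = species[1] if sp_first == species[0] else species[0]
    venns = {}
    venn_objects = {}
    for target in config.supporting_labels:
        a_up, a_down = supporting_de(
            merged, sp_first, config.presupporting_label, target, config.de)
        b_up, b_down = supporting_de(
            merged, sp_second, config.presupporting_label, target, config.de)
        venn = cross_species_venn(a_up, a_down, b_up, b_down, omap)
        venn.validate()
        venns[target] = venn.summary()
        venn_objects[target] = venn
        for direction in ("up", "down"):
            for cell, genes in venn.members[direction].items():
                pd.Series(sorted(genes)).to_csv(
                    outdir / f"venn_{target}_{direction}_{cell}.tsv",
                    sep="\t", index=False, header=False)
    done(venns)

    # --- signatures -------------------------------------------------------
    done = stage("signatures")
    sig_summary = {}
    models = {}
    for sp in species:
        sub = merged[merged.obs["species"] == sp]
        idx = balanced_sample(sub.obs["cell_type"], config.n_train_per_type,
                              seed=config.seed)
        train = sub[idx].copy()
        train.uns = dict(sub.uns)
        for target in config.signature_targets:
            m = fit_signature(train, target, l1_ratio=config.l1_ratio,
                              penalty=config.penalty, seed=config.seed)
            models[(sp, target)] = m
    for target in config.signature_targets:
        sig_a = extract_signature(models[(species[0], target)])
        sig_b = extract_signature(models[(species[1], target)])
        # signatures are in canonical merged-space IDs; map to species IDs
        side = merged.uns["species_sides"]
        var = merged.var
        id_a = [var.loc[g, f"gene_{side[species[0]]}"] for g in sig_a]
        id_b = [var.loc[g, f"gene_{side[species[1]]}"] for g in sig_b]
        if side[species[0]] == "a":
            ov = signature_overlap(id_a, id_b, omap)
        else:
            ov = signature_overlap(id_b, id_a, omap)
        sig_summary[target] = {
            species[0]: len(sig_a), species[1]: len(sig_b),
            "overlap": ov.summary(),
        }
        pd.DataFrame({"gene": sig_a}).to_csv(
            outdir / f"signature_{species[0]}_{target}.tsv", sep="\t", index=False)
        pd.DataFrame({"gene": sig_b}).to_csv(
            outdir / f"signature_{species[1]}_{target}.tsv", sep="\t", index=False)
        scores = score_cells(models[(species[0], target)], merged)
        scores.to_csv(outdir / f"scores_{species[0]}_{target}.tsv", sep="\t")
    done(sig_summary)

    # --- enrichment -------------------------------------------------------
    if config.gmt and config.run_enrichment:
        done = stage("enrich")
        coll = read_gmt(config.gmt)
        enr_summary = {}
        for target, venn in venn_objects.items():
            query = venn.members["up"]["shared_a"]
            if not query or not (query & coll.universe):
                enr_summary[target] = {
                    "n_hits": 0,
                    "note": "shared up set empty or outside the collection universe",
                }
                continue
            res = hypergeom_ora(query, coll)
            res.to_csv(outdir / f"enrichment_{target}.tsv", sep="\t", index=False)
            enr_summary[target] = {
                "n_terms": int(len(res)),
                "n_hits": int((res["q"] <= 0.05).sum()),
            }
        done(enr_summary)

    report["n_stages"] = len(report["stages"])
    # re-validate Venn arithmetic at report time
    for target, v in report["stages"]["de_venn"]["summary"].items():
        for d in ("up", "down"):
            s = v[d]
            if s["a_exclusive"] + s["b_exclusive"] + s["shared"] != s["total"]:
                raise RuntimeError(f"inconsistent Venn partition for {target}/{d}")
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
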