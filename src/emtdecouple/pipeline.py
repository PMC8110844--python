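"""End-to-end orchestration with a reproducible run manifest.

``run_pipeline`` drives the stages synth -> esg -> deconv -> annotate ->
cross-cancer scores -> clinical on a synthetic cohort (or user-supplied
inputs prepared to the same shapes), writing every stage output plus a
manifest that records the config snapshot, seeds and all tunable parameters,
so a deterministic re-run reproduces the outputs bit-identically.

A QC exclusion (confounder slope or conflicting validation measures) halts
the pipeline with :class:`QCExclusionError` unless ``force`` is set.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import clinical as clin
from . import cross_cancer as xc
from . import deconvolve as dc
from . import esg as esg_mod
from . import io as eio
from . import sc as sc_mod
from .containers import ExpressionMatrix
from .synthetic import (SyntheticConfig, generate_bulk_cohort,
                        generate_cellline_profiles, generate_sc_dataset,
                        planted_gene_sets)


class QCExclusionError(RuntimeError):
    """Raised when a dataset fails robustness / annotation quality control."""


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    min_genes_detected: int = 200        # complexity filter for synthetic cells
    esg_top_frac: float = 0.01
    esg_tpm_threshold: float = 5.0
    quantile_q: float = 0.75
    n_select: int | None = None
    confounder_overrides: dict[str, float] | None = None
    track_window: int = 30
    scoring_bins: int = 25
    scoring_controls: int = 100
    alpha: float = 0.05
    fdr_scope: str = "per_feature"
    force: bool = False

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        synth = SyntheticConfig(**payload.pop("synthetic", {}))
        return cls(synthetic=synth, **payload)


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    qc: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _config_snapshot(config: PipelineConfig) -> dict:
    payload = dataclasses.asdict(config)
    return payload


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_snapshot(config), seed=config.synthetic.seed)

    # ------------------------------------------------------------- synth
    sc_tpm, meta, positions, truth = generate_sc_dataset(config.synthetic)
    bulk = generate_bulk_cohort(config.synthetic, truth)
    celllines = generate_cellline_profiles(config.synthetic, truth)
    gene_sets = planted_gene_sets(truth, seed=config.synthetic.seed)

    eio.write_expression_tsv(sc_tpm, out / "sc_tpm.tsv")
    meta.to_csv(out / "sc_meta.tsv", sep="\t", index=False)
    eio.write_bed(positions, out / "gene_positions.bed")
    eio.write_expression_tsv(bulk.expression, out / "bulk_log2.tsv")
    bulk.purity.to_csv(out / "purity.tsv", sep="\t")
    bulk.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    eio.write_expression_tsv(celllines, out / "celllines_log2.tsv")
    eio.write_gmt(gene_sets, out / "gene_sets.gmt")
    eio.write_ground_truth(truth, out / "ground_truth.json")
    manifest.stages["synth"] = {"n_cells": sc_tpm.shape[1], "n_genes": sc_tpm.shape[0],
                                "n_samples": bulk.expression.shape[1]}

    # --------------------------------------------------------------- esg
    sc_log, meta = sc_mod.filter_low_complexity_cells(
        sc_mod.normalize_tpm(sc_tpm), config.min_genes_detected, meta)
    bulk_corr = esg_mod.bulk_marker_correlated_genes(bulk.expression,
                                                    top_frac=config.esg_top_frac)
    hallmark, tan = gene_sets.values()
    esgs = esg_mod.assemble_esgs(hallmark, tan, bulk_corr)
    esgs = esg_mod.filter_esgs_by_celltype(esgs, sc_log, meta)
    focal_cells = meta.loc[meta["cell_type"].isin(["cancer", "CAF"]), "cell_id"]
    sc_tpm_filtered = sc_tpm.subset_samples(sc_log.sample_ids)
    esgs = esg_mod.filter_esgs_by_expression(esgs, sc_tpm_filtered,
                                             config.esg_tpm_threshold,
                                             over=focal_cells)
    esg_mod.write_esg_tsv(esgs, out / "esgs.tsv")
    manifest.stages["esg"] = {"n_assembled": len(esgs.genes),
                              "n_kept": len(esgs.kept_genes()),
                              "top_frac": config.esg_top_frac,
                              "tpm_threshold": config.esg_tpm_threshold}

    # ------------------------------------------------------------- deconv
    result = dc.run_deconvolution(
        bulk.expression, esgs.kept_genes(),
        markers_per_type=truth.confounder_genes,
        quantile_q=config.quantile_q, n_select=config.n_select,
        overrides=config.confounder_overrides, seed=None)
    result.table.to_csv(out / "deconv_ordered.tsv", sep="\t", index_label="gene")
    result.corr.to_csv(out / "deconv_corr.tsv", sep="\t")
    manifest.stages["deconv"] = dict(result.metadata)

    # ----------------------------------------------------------- annotate
    order = result.ordered_genes
    tracks = ann.ValidationTracks(
        purity=ann.purity_track(bulk.expression, order, bulk.purity,
                                window=config.track_window),
        cellline=ann.cellline_track(bulk.expression.data.mean(axis=1),
                                    celllines.data.mean(axis=1), order,
                                    window=config.track_window),
        sc=ann.sc_track(sc_log, meta, order, window=config.track_window),
    )
    annotation = ann.annotate_clusters(result, tracks)
    pemt_end = next(e for e, label in annotation.labels.items() if label == "pEMT")
    qc = ann.robustness_qc(result.confounder_model, result, tracks,
                           pemt_end=pemt_end)
    manifest.qc = {
        "labels": annotation.labels, "votes": annotation.votes,
        "confidence": annotation.confidence, "flags": annotation.flags,
        "annotation_excluded": annotation.excluded,
        "slopes": qc.slopes.to_dict(), "qc_exclude": qc.exclude,
        "within_cluster": qc.within_cluster, "between_cluster": qc.between_cluster,
    }
    tracks.purity.to_csv(out / "purity_track.tsv", sep="\t", index_label="gene")
    tracks.cellline.to_csv(out / "cellline_track.tsv", sep="\t", index_label="gene")
    if (annotation.excluded or qc.exclude) and not config.force:
        manifest.write(out / "manifest.json")
        raise QCExclusionError(
            f"dataset excluded by QC (annotation={annotation.excluded}, "
            f"slopes={qc.slopes.min():.3f})")

    caf_end = "endB" if pemt_end == "endA" else "endA"
    top_pemt = result.top_genes(pemt_end, 20)
    top_caf = result.top_genes(caf_end, 20)
    manifest.stages["annotate"] = {"top_pemt": top_pemt, "top_caf": top_caf}

    # ------------------------------------------------------------ xcancer
    scores = xc.pemt_caf_scores_one_type(result.residualized, top_pemt, top_caf)
    scores.rename("pemt_caf_score").to_csv(out / "pemt_caf_scores.tsv", sep="\t")
    manifest.stages["xcancer"] = {"n_scored": int(scores.notna().sum())}

    # ----------------------------------------------------------- clinical
    cfg = sc_mod.ScoringConfig(n_bins=config.scoring_bins,
                               n_controls=config.scoring_controls,
                               seed=config.synthetic.seed)
    pemt_scores = sc_mod.score_signature(bulk.expression, top_pemt, cfg)
    caf_scores = sc_mod.score_signature(bulk.expression, top_caf, cfg)
    associations = clin.run_clinical_associations(
        pemt_scores, caf_scores, bulk.clinical, alpha=config.alpha,
        fdr_scope=config.fdr_scope)
    associations.to_csv(out / "clinical_associations.tsv", sep="\t", index=False)
    manifest.stages["clinical"] = {
        "n_tests": int(associations["p_value"].notna().sum()),
        "n_significant": int(associations["significant"].eq(True).sum()),
        "alpha": config.alpha, "fdr_scope": config.fdr_scope,
    }

    for p in sorted(out.glob("*")):
        manifest.outputs[p.name] = str(p)
    manifest.write(out / "manifest.json")
    return manifest
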