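"""End-to-end orchestration: simulate -> QC -> ambient -> cluster -> markers
-> ablation -> male/female comparison -> report.

Each stage is a pure function of (inputs, config, seed); per-stage seeds are
derived from the base seed by stable hashing of the stage name, so re-running
one stage never perturbs another.
"""
from __future__ import annotations

import json
import warnings
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ablation as abl
from . import ambient, cluster, compare, markers, qc
from .iocore import CountMatrix, PipelineConfig, write_report
from .simdata import (MITO_GENES, NONEYE_MARKERS, SimConfig,
                      generate_retina_dataset, write_dataset)

STAGES = ("simulate", "qc", "cluster", "markers", "ablate", "compare")


def stage_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage seed (independent of Python's salted hash)."""
    mix = np.random.SeedSequence([int(base_seed), zlib.crc32(stage.encode())])
    return int(mix.generate_state(1)[0] % (2 ** 31))


def forbidden_map_from_annotation(annotation: pd.DataFrame,
                                  panels: Mapping | None = None
                                  ) -> dict:
    """Cluster -> forbidden opsins, from each cluster's annotated type."""
    panels = cluster.DEFAULT_PANELS if panels is None else panels
    out = {}
    for k, row in annotation.iterrows():
        ty = row["type"]
        if ty in panels:
            forb = list(panels[ty].get("forbidden", []))
            # a cluster's own dominant opsin never goes in its forbidden set,
            # but the opposite-subtype opsin of R7/R8 clusters does --
            # except for dorsal-third (both R7 opsins) and dorsal-rim
            # (Rh3-only) clusters
            if row.get("dra", False):
                forb = [g for g in forb if g != "Rh3"]
            elif ty == "R7" and not row.get("dorsal3", False):
                forb = forb + (["Rh4"] if row["subtype"] == "pale" else ["Rh3"])
            elif ty == "R8":
                forb = forb + (["Rh6"] if row["subtype"] == "pale" else ["Rh5"])
            out[k] = forb
        else:
            out[k] = []
    return out


def qc_and_ambient(matrix: CountMatrix, config: PipelineConfig,
                   seed: int) -> dict:
    """Metrics, threshold filter, non-eye removal, soup correction.

    Returns a dict with the corrected matrix, kept barcodes, QC metrics,
    the preliminary clustering used for non-eye removal and soup estimates.
    """
    metrics = qc.compute_qc_metrics(matrix, MITO_GENES)
    kept = qc.filter_cells(metrics, config.mito_max, config.gene_min,
                           config.gene_max)
    keep_mask = np.isin(matrix.barcodes, list(kept))
    filtered = matrix.subset_cells(keep_mask)

    prelim = cluster.run_clustering(filtered, config, seed=seed)
    surviving = qc.drop_noneye_clusters(filtered, prelim.labels,
                                        NONEYE_MARKERS,
                                        config.noneye_frac_threshold)
    eye_mask = np.isin(filtered.barcodes, list(surviving))
    eye = filtered.subset_cells(eye_mask)
    eye_labels = prelim.labels[eye_mask]

    soup = ambient.estimate_soup_profile(eye)
    ann = cluster.annotate_clusters(prelim.expr[eye_mask], eye_labels,
                                    eye.gene_symbols,
                                    counts=eye.densify())
    forbidden = forbidden_map_from_annotation(ann)
    contamination = ambient.estimate_contamination(eye, eye_labels, forbidden,
                                                   soup)
    corrected = ambient.correct_ambient(eye, soup, contamination, eye_labels,
                                        seed=seed)
    return {
        "metrics": metrics,
        "kept_barcodes": kept,
        "filtered": filtered,
        "eye": eye,
        "corrected": corrected,
        "prelim_labels": eye_labels,
        "soup": soup,
        "contamination": contamination,
    }


def marker_stage(result: cluster.ClusteringResult, matrix: CountMatrix,
                 config: PipelineConfig) -> dict:
    """Type-level marker calling, specificity classes, shared R7/8 markers."""
    type_labels = result.cell_types
    counts = matrix.densify()
    table = markers.rank_markers_wilcoxon(
        result.expr, type_labels, counts=counts,
        gene_symbols=matrix.gene_symbols,
        min_pct=config.min_pct, logfc_threshold=config.logfc_threshold)
    classes = markers.classify_specificity(
        result.expr, type_labels, table, tau=config.tau,
        gene_symbols=matrix.gene_symbols)
    table = table.merge(classes[["gene", "cluster", "specificity_class"]],
                        on=["gene", "cluster"], how="left")
    shared = []
    present = set(pd.unique(np.asarray(type_labels)))
    if {"R7", "R8"} <= present:
        shared = markers.find_shared_pair_markers(
            result.expr, type_labels, ("R7", "R8"), tau=config.tau,
            gene_symbols=matrix.gene_symbols)
    return {"table": table, "shared_R7_R8": shared}


def subtype_ratio_tests(result: cluster.ClusteringResult,
                        p0: float = 0.30) -> dict:
    """Pale:yellow ratio tests from annotated R7/R8 cluster sizes."""
    out = {}
    ann = result.annotation
    for ty in ("R7", "R8"):
        n_pale = n_yellow = 0
        for k, row in ann.iterrows():
            if row["type"] != ty:
                continue
            n = int((result.labels == k).sum())
            if row["subtype"] == "pale":
                n_pale += n
            elif row["subtype"] == "yellow":
                n_yellow += n
        if n_pale + n_yellow > 0:
            out[ty] = compare.ratio_test_binomial(n_pale, n_yellow, p0).to_dict()
    return out


def run_full_pipeline(sim_config: SimConfig | None = None,
                      config: PipelineConfig | None = None,
                      outdir: str | Path | None = None,
                      with_embedding: bool | None = None) -> dict:
    """Synthetic dataset -> all analysis stages -> report dict.

    When ``outdir`` is given, stage artifacts (dataset, QC table, labels,
    marker tables, ablation report, report.json) are written there.
    """
    sim_config = sim_config or SimConfig()
    cfg = config or PipelineConfig()
    cfg.validate()
    base = cfg.seed
    outdir = Path(outdir) if outdir is not None else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    matrix, annotation, truth = generate_retina_dataset(sim_config)
    if outdir:
        write_dataset(outdir / "dataset", matrix, annotation, truth, sim_config)

    # --- qc + ambient -----------------------------------------------------
    qa = qc_and_ambient(matrix, cfg, stage_seed(base, "qc"))
    corrected = qa["corrected"]
    truth_kept = truth.cells.loc[corrected.barcodes]
    if outdir:
        qa["metrics"].to_csv(outdir / "qc_metrics.tsv", sep="\t")

    # --- cluster ----------------------------------------------------------
    embed = cfg.run_embedding if with_embedding is None else with_embedding
    res = cluster.run_clustering(corrected, cfg, with_embedding=embed,
                                 seed=stage_seed(base, "cluster"))
    if outdir:
        lab = pd.DataFrame({"cluster": res.labels, "type": res.cell_types},
                           index=pd.Index(corrected.barcodes, name="barcode"))
        lab.to_csv(outdir / "clusters.tsv", sep="\t")
        res.annotation.to_csv(outdir / "annotation.tsv", sep="\t")
        if res.embedding is not None:
            pd.DataFrame(res.embedding, columns=["umap1", "umap2"],
                         index=pd.Index(corrected.barcodes, name="barcode")
                         ).to_csv(outdir / "embedding.tsv", sep="\t")

    # --- markers ----------------------------------------------------------
    mk = marker_stage(res, corrected, cfg)
    if outdir:
        mk["table"].to_csv(outdir / "markers.tsv", sep="\t", index=False)

    # --- ablation ---------------------------------------------------------
    ablation_out = []
    if cfg.run_ablation:
        reports = abl.run_ablation_experiment(
            corrected, res, truth_kept["type"].to_numpy(),
            truth_kept["subtype"].to_numpy(), config=cfg,
            seed=stage_seed(base, "ablate"))
        ablation_out = [r.to_dict() for r in reports]
        if outdir:
            (outdir / "ablation.json").write_text(
                json.dumps(ablation_out, indent=1))

    # --- compare ----------------------------------------------------------
    compare_out: dict = {}
    tp = truth_kept["timepoint"].to_numpy()
    if len(pd.unique(tp)) >= 2:
        tmix = compare.timepoint_mixing(res.labels, tp)
        metrics_kept = qa["metrics"].loc[corrected.barcodes]
        trend = compare.aging_trend(metrics_kept, tp,
                                    order=list(sim_config.timepoints))
        compare_out["timepoint_mixing"] = tmix.reset_index()
        compare_out["aging_trend"] = trend.reset_index()
        compare_out["depth_decreasing"] = trend.attrs["decreasing"]
    compare_out["ratio_tests"] = subtype_ratio_tests(res, sim_config.pale_prob)

    report = {
        "qc": {
            "n_input_cells": matrix.n_cells,
            "n_after_threshold_filter": qa["filtered"].n_cells,
            "n_after_noneye_removal": qa["eye"].n_cells,
            "median_genes": float(qa["metrics"]["n_genes"].median()),
            "median_counts": float(qa["metrics"]["total_counts"].median()),
            "mean_mito_fraction": float(qa["metrics"]["mito_fraction"].mean()),
        },
        "ambient": {
            "rho_by_cluster": qa["contamination"].table["rho"].dropna().to_dict(),
            "top_soup_gene": str(corrected.gene_symbols[
                int(np.argmax(qa["soup"].s))]),
        },
        "clusters": {
            "n_communities": int(len(np.unique(res.labels))),
            "annotation": res.annotation.reset_index(),
            "type_counts": pd.Series(res.cell_types).value_counts().to_dict(),
        },
        "markers": {
            "n_called": int(len(mk["table"])),
            "class_counts": mk["table"]["specificity_class"]
                .value_counts().to_dict(),
            "shared_R7_R8": mk["shared_R7_R8"],
        },
        "ablation": ablation_out,
        "compare": compare_out,
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(cfg).items()},
        "seeds": {s: stage_seed(base, s) for s in STAGES},
    }
    if outdir:
        write_report(report, outdir / "report.json")
    return report
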