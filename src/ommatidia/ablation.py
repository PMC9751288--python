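"""Gene-ablation clustering-contribution experiment.

Deleting the inner-photoreceptor Rhodopsins from the counts and reclustering
quantifies how much those genes contribute to cluster separation.  Reference
labels are transferred (not re-inferred) to the ablated data and two
statistics are computed in the ablated PC space:

* the mixing index M for a pair of classes: mean same-label fraction among
  each cell's k nearest neighbours, normalized so 1 = fully separated and
  0 = what random mixing of the two classes would give;
* the adjusted Rand index between reference cluster labels and de-novo
  communities, restricted to a type subset (e.g. pigment/cone), measuring
  whether untouched cell types keep their cluster structure.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.neighbors import NearestNeighbors

from .cluster import (ClusteringResult, PipelineConfig, build_snn_graph,
                      compute_pca, detect_communities, normalize_log_cp10k,
                      select_hvgs)
from .iocore import CountMatrix

DEFAULT_GENE_SETS: tuple[tuple[str, ...], ...] = (
    ("Rh3", "Rh4"),
    ("Rh5", "Rh6"),
    ("Rh3", "Rh4", "Rh5", "Rh6"),
    ("ninaE",),
    ("ninaE", "Rh3", "Rh4", "Rh5", "Rh6"),
)


def remove_genes(matrix: CountMatrix, genes: Sequence[str]) -> CountMatrix:
    """Delete gene columns by symbol; absent symbols warn, barcodes unchanged."""
    present = set(matrix.gene_symbols)
    missing = [g for g in genes if g not in present]
    if missing:
        warnings.warn(f"genes to remove not present: {missing}")
    drop = set(genes) - set(missing)
    keep = np.array([i for i, s in enumerate(matrix.gene_symbols)
                     if s not in drop], dtype=int)
    return matrix.subset_genes(keep)


def transfer_reference_labels(reference_barcodes: Sequence[str],
                              reference_labels: Sequence,
                              barcodes: Sequence[str]) -> np.ndarray:
    """Carry per-cell labels from the reference run to the ablated data.

    Labels follow barcodes, never positions; barcode mismatch raises with
    the differing barcodes listed.
    """
    ref = dict(zip(reference_barcodes, reference_labels))
    barcodes = list(barcodes)
    missing = [b for b in barcodes if b not in ref]
    extra = set(reference_barcodes) - set(barcodes)
    if missing or extra:
        raise ValueError(
            f"barcode mismatch: {len(missing)} ablated barcodes absent from "
            f"reference (e.g. {missing[:5]}), {len(extra)} reference barcodes "
            f"absent from ablated data (e.g. {sorted(extra)[:5]})")
    return np.array([ref[b] for b in barcodes], dtype=object)


def mixing_index(pca: np.ndarray, labels: Sequence, pair: tuple,
                 k: int = 20) -> float:
    """Normalized kNN same-label score for two classes.

    Restricted to cells of the two classes; for each such cell the fraction
    of its k nearest neighbours (in the supplied PC space) with the same
    label is averaged to S_obs, and M = (S_obs - S_null) / (1 - S_null)
    where S_null = p_A^2 + p_B^2 is the expectation under random mixing.
    """
    labels = np.asarray(labels, dtype=object)
    a, b = pair
    mask = (labels == a) | (labels == b)
    if not (labels == a).any() or not (labels == b).any():
        raise ValueError(f"both classes of pair {pair} must be present")
    sub = np.asarray(pca, dtype=float)[mask]
    lab = labels[mask] == a
    n_a, n_b = int(lab.sum()), int((~lab).sum())
    if min(n_a, n_b) < k + 1:
        raise ValueError(
            f"pair {pair}: class sizes ({n_a}, {n_b}) must each be >= k+1={k + 1}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(sub)
    _, idx = nn.kneighbors(sub)
    same = (lab[idx[:, 1:]] == lab[:, None]).mean()
    p_a = n_a / (n_a + n_b)
    s_null = p_a ** 2 + (1 - p_a) ** 2
    return float((same - s_null) / (1 - s_null))


def cluster_ari(labels_a: Sequence, labels_b: Sequence,
                restrict_to: Sequence | None = None,
                type_labels: Sequence | None = None) -> float:
    """Adjusted Rand index by the standard pair-counting formula.

    When ``restrict_to`` is given, only cells whose ``type_labels`` entry is
    in that set are compared.
    """
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if restrict_to is not None:
        if type_labels is None:
            raise ValueError("restrict_to requires type_labels")
        mask = np.isin(np.asarray(type_labels, dtype=object),
                       list(restrict_to))
        a, b = a[mask], b[mask]
    n = len(a)
    if n < 2:
        raise ValueError("need at least two cells for an ARI")
    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    sum_comb = comb(ct, 2).sum()
    sum_a = comb(ct.sum(axis=1), 2).sum()
    sum_b = comb(ct.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


@dataclass
class AblationReport:
    """Outcome of one gene-set removal."""

    removed_genes: tuple[str, ...]
    mixing: dict           # pair name -> M (or None when undefined)
    ari_untouched: float   # ARI vs reference over pigment + cone cells
    baseline_mixing: dict  # same pairs on the unablated reference

    def to_dict(self) -> dict:
        return {
            "removed_genes": list(self.removed_genes),
            "mixing": self.mixing,
            "ari_untouched": self.ari_untouched,
            "baseline_mixing": self.baseline_mixing,
        }


MIXING_PAIRS: dict[str, tuple[str, str]] = {
    "R7pale_vs_R7yellow": ("R7-pale", "R7-yellow"),
    "R8pale_vs_R8yellow": ("R8-pale", "R8-yellow"),
    "R7_vs_R8": ("R7", "R8"),
    "innerPR_vs_R16": ("R7+R8", "R1-6"),
    "R16_vs_rest": ("R1-6", "rest"),
}


def _pair_labels(types: np.ndarray, subtypes: np.ndarray,
                 pair_name: str) -> np.ndarray:
    """Per-cell labels for one mixing pair (uses subtype or type as needed)."""
    if pair_name in ("R7pale_vs_R7yellow", "R8pale_vs_R8yellow"):
        return subtypes
    if pair_name == "R7_vs_R8":
        return types
    if pair_name == "innerPR_vs_R16":
        lab = types.astype(object).copy()
        lab[np.isin(types, ("R7", "R8"))] = "R7+R8"
        return lab
    if pair_name == "R16_vs_rest":
        lab = types.astype(object).copy()
        lab[types != "R1-6"] = "rest"
        return lab
    raise KeyError(pair_name)


def _mixing_suite(pca: np.ndarray, types: np.ndarray,
                  subtypes: np.ndarray, k: int) -> dict:
    out = {}
    for name, pair in MIXING_PAIRS.items():
        lab = _pair_labels(types, subtypes, name)
        try:
            out[name] = mixing_index(pca, lab, pair, k=k)
        except ValueError as e:
            warnings.warn(f"mixing {name} undefined: {e}")
            out[name] = None
    return out


def ablated_pc_space(matrix: CountMatrix, genes: Sequence[str],
                     config: PipelineConfig, seed: int) -> np.ndarray:
    """Remove genes, re-run normalize -> HVG -> PCA with identical parameters."""
    ablated = remove_genes(matrix, genes)
    hvgs = select_hvgs(ablated, config.n_hvg)
    if config.pca_scale == "pearson":
        scores, _, _ = compute_pca(ablated, hvgs, config.n_dims, "pearson",
                                   config.pearson_theta, seed=seed)
    else:
        expr = normalize_log_cp10k(ablated)
        scores, _, _ = compute_pca(expr, hvgs, config.n_dims, "zscore",
                                   seed=seed)
    return scores


def run_ablation_experiment(matrix: CountMatrix, reference: ClusteringResult,
                            cell_types: Sequence, cell_subtypes: Sequence,
                            gene_sets: Sequence[Sequence[str]] = DEFAULT_GENE_SETS,
                            config: PipelineConfig | None = None,
                            seed: int = 0) -> list[AblationReport]:
    """Remove each gene set, recluster, transfer labels, quantify collapse.

    ``cell_types``/``cell_subtypes`` are the per-cell annotations from the
    reference run (they are transferred, never re-inferred).  For each set
    the full normalize -> HVG -> PCA -> SNN -> Leiden stack is re-run with
    identical parameters and seed; mixing indices are computed in the
    ablated PC space and the ARI against the reference cluster labels is
    restricted to the untouched pigment and cone cells.
    """
    cfg = config or PipelineConfig()
    types = np.asarray(cell_types, dtype=object)
    subtypes = np.asarray(cell_subtypes, dtype=object)
    baseline = _mixing_suite(reference.pca, types, subtypes, cfg.neighbors_k)
    reports = []
    for genes in gene_sets:
        scores = ablated_pc_space(matrix, genes, cfg, seed)
        graph = build_snn_graph(scores, cfg.neighbors_k, cfg.snn_prune)
        denovo = detect_communities(graph, cfg.resolution, seed=seed)
        mixing = _mixing_suite(scores, types, subtypes, cfg.neighbors_k)
        ari = cluster_ari(reference.labels, denovo,
                          restrict_to=("pigment1", "pigment23", "cone"),
                          type_labels=types)
        reports.append(AblationReport(tuple(genes), mixing, ari, baseline))
    return reports
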