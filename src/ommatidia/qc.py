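"""Per-cell quality control and non-eye cell removal.

Cells are kept when their detected-gene count lies inclusively between
``gene_min`` and ``gene_max`` and their mitochondrial fraction is strictly
below ``mito_max`` (the published thresholds word the gene bound as
"between" and the mitochondrial bound as "<", and the filter follows that
wording).  Non-eye cells (brain neurons marked by fne, glia by moody and
repo) are removed at cluster level: any cluster in which one of those
markers is detected in at least ``frac_threshold`` of cells is dropped.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .iocore import CountMatrix
from .simdata import NONEYE_MARKERS


def compute_qc_metrics(matrix: CountMatrix,
                       mito_genes: Iterable[str]) -> pd.DataFrame:
    """Per-cell total_counts, n_genes and mito_fraction.

    ``mito_genes`` are gene symbols; symbols absent from the matrix are
    dropped with a warning.  Cells with zero counts get mito_fraction 0.
    """
    mito_genes = list(mito_genes)
    present = [g for g in mito_genes if g in set(matrix.gene_symbols)]
    missing = sorted(set(mito_genes) - set(present))
    if missing:
        warnings.warn(f"mito genes absent from matrix: {missing}")
    if not present:
        warnings.warn("empty mitochondrial gene set; mito_fraction will be 0")
    total = matrix.library_sizes().astype(float)
    n_genes = np.asarray((matrix.X > 0).sum(axis=1)).ravel()
    if present:
        idx = matrix.gene_index(present)
        mito = np.asarray(matrix.X[:, idx].sum(axis=1)).ravel().astype(float)
    else:
        mito = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame({
        "total_counts": total.astype(int),
        "n_genes": n_genes.astype(int),
        "mito_fraction": frac,
    }, index=pd.Index(matrix.barcodes, name="barcode"))


def filter_cells(metrics: pd.DataFrame, mito_max: float,
                 gene_min: int, gene_max: int) -> set[str]:
    """Barcodes with gene_min <= n_genes <= gene_max and mito_fraction < mito_max."""
    keep = ((metrics["n_genes"] >= gene_min)
            & (metrics["n_genes"] <= gene_max)
            & (metrics["mito_fraction"] < mito_max))
    kept = set(metrics.index[keep])
    if not kept:
        warnings.warn("cell filter kept zero cells")
    return kept


def detection_fraction(matrix: CountMatrix, labels: Sequence,
                       gene: str) -> pd.Series:
    """Per-cluster fraction of cells with a nonzero count for ``gene``."""
    col = matrix.gene_index([gene])[0]
    detected = np.asarray((matrix.X[:, [col]] > 0).todense()).ravel()
    return pd.Series(detected).groupby(np.asarray(labels, dtype=object)).mean()


def drop_noneye_clusters(matrix: CountMatrix, cluster_labels: Sequence,
                         noneye_markers: Iterable[str] = NONEYE_MARKERS,
                         frac_threshold: float = 0.5) -> set[str]:
    """Remove clusters expressing brain-neuron or glial markers.

    A cluster is dropped when the detection fraction of any non-eye marker
    reaches ``frac_threshold``; returns the surviving barcodes.
    """
    labels = np.asarray(cluster_labels, dtype=object)
    if len(labels) != matrix.n_cells:
        raise ValueError("cluster labels length does not match matrix")
    bad_clusters: set = set()
    for g in noneye_markers:
        try:
            frac = detection_fraction(matrix, labels, g)
        except KeyError:
            warnings.warn(f"non-eye marker {g!r} absent from matrix; skipped")
            continue
        bad_clusters |= set(frac.index[frac >= frac_threshold])
    keep = ~np.isin(labels, sorted(bad_clusters))
    return set(matrix.barcodes[keep])
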