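"""Male/female integration, the sex-specific marker screen, timepoint-mixing
and aging-depth statistics, and pale:yellow subtype-ratio tests.

Batch integration is a deliberately simple, transparent stand-in for
Harmony: iterate joint clustering and within-cluster translation of each
batch's cells so the batch centroids coincide with the cluster centroid.
Sufficient for offset-style batch effects, which is all the sex comparison
requires.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.cluster import KMeans

from .iocore import CountMatrix
from .markers import EXACT_MAX_N, _rank_test_vectorized, wilcoxon_exact_p


# ---------------------------------------------------------------------------
# merging and batch correction

def merge_batches(matrices: Sequence[CountMatrix],
                  batch_labels: Sequence[str]
                  ) -> tuple[CountMatrix, np.ndarray]:
    """Outer-join gene lists (zero-filling absentees) and stack cells.

    Barcodes are suffixed with their batch label so the merged barcode set
    is unique even when batches share barcodes.
    """
    if len(matrices) != len(batch_labels) or len(matrices) < 2:
        raise ValueError("need >= 2 matrices with matching batch labels")
    all_ids: list[str] = []
    id_to_symbol: dict[str, str] = {}
    for m in matrices:
        for gid, gsym in zip(m.gene_ids, m.gene_symbols):
            if gid not in id_to_symbol:
                all_ids.append(gid)
                id_to_symbol[gid] = gsym
    union_n = len(all_ids)
    if any(m.n_genes != union_n for m in matrices):
        warnings.warn("gene lists differ between batches; absent genes "
                      "zero-filled")
    col_of = {gid: j for j, gid in enumerate(all_ids)}
    blocks, barcodes, batch = [], [], []
    for m, b in zip(matrices, batch_labels):
        cols = np.array([col_of[g] for g in m.gene_ids], dtype=int)
        block = sp.lil_matrix((m.n_cells, union_n), dtype=np.int64)
        block[:, cols] = m.X
        blocks.append(block.tocsr())
        barcodes.extend([f"{bc}-{b}" for bc in m.barcodes])
        batch.extend([b] * m.n_cells)
    merged = CountMatrix(sp.vstack(blocks).tocsr(),
                         np.array(barcodes, dtype=object),
                         np.array(all_ids, dtype=object),
                         np.array([id_to_symbol[g] for g in all_ids],
                                  dtype=object))
    return merged, np.array(batch, dtype=object)


def correct_batch_centroids(pca: np.ndarray, batch: Sequence,
                            n_clusters: int = 20, max_iter: int = 10,
                            tol: float = 1e-3, min_cells: int = 10,
                            seed: int = 0) -> np.ndarray:
    """Iterative within-cluster centroid alignment of batches.

    The batches are first translated so their global centroids coincide
    (this alone removes a constant offset exactly, and prevents the joint
    clustering from simply separating the batches); each following
    iteration jointly clusters the current scores (k-means, seeded) and,
    within every cluster, translates each batch's cells so that the batch
    centroid coincides with the cluster centroid.  Batches with fewer than
    ``min_cells`` cells in a cluster are left untouched.  Stops when the
    largest translation is below ``tol``.
    """
    X = np.asarray(pca, dtype=float).copy()
    batch = np.asarray(batch, dtype=object)
    names = pd.unique(batch)
    if len(names) < 2:
        return X
    for name in names:
        if not (batch == name).any():
            raise ValueError(f"batch {name!r} has no cells")
    grand = X.mean(axis=0)
    for name in names:
        rows = batch == name
        X[rows] += grand - X[rows].mean(axis=0)
    k = int(min(n_clusters, len(X)))
    for _ in range(max_iter):
        km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(X)
        moved = 0.0
        for c in range(k):
            in_c = km.labels_ == c
            if not in_c.any():
                continue
            centroid = X[in_c].mean(axis=0)
            for name in names:
                rows = in_c & (batch == name)
                if rows.sum() < min_cells:
                    continue
                shift = centroid - X[rows].mean(axis=0)
                X[rows] += shift
                moved = max(moved, float(np.linalg.norm(shift)))
        if moved < tol:
            break
    return X


# ---------------------------------------------------------------------------
# sex-specific screen

VERDICTS = ("sex_specific", "fold_different", "pattern_equivalent")


def sex_specific_screen(expr: np.ndarray, labels: Sequence, sex: Sequence,
                        counts: np.ndarray | None = None,
                        gene_symbols: Sequence[str] | None = None,
                        alpha: float = 0.05, fold_thr: float = 2.0,
                        tau_hi: float = 0.25, tau_lo: float = 0.05,
                        exclude_clusters: Sequence = (),
                        min_cells: int = 3) -> pd.DataFrame:
    """Male-vs-female rank test per cluster with a three-way verdict.

    Candidates are genes with Bonferroni-adjusted p < alpha in a cluster.
    A candidate is ``sex_specific`` when detected in >= tau_hi of one sex
    and <= tau_lo of the other, ``fold_different`` when the mean-CP10K
    (+1 pseudocount) ratio exceeds ``fold_thr`` either way, otherwise
    ``pattern_equivalent``.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels, dtype=object)
    sex = np.asarray(sex, dtype=object)
    genes = (np.asarray(gene_symbols, dtype=object) if gene_symbols is not None
             else np.array([f"g{i}" for i in range(expr.shape[1])],
                           dtype=object))
    if counts is None:
        cp10k = np.expm1(expr)
    else:
        C = np.asarray(counts, dtype=float)
        cp10k = 1e4 * C / np.maximum(C.sum(axis=1, keepdims=True), 1.0)
    detected = expr > 0
    excluded = set(exclude_clusters)
    records = []
    for k in pd.unique(labels):
        if k in excluded:
            continue
        in_k = labels == k
        male = in_k & (sex == "M")
        fem = in_k & (sex == "F")
        if male.sum() < min_cells or fem.sum() < min_cells:
            warnings.warn(f"cluster {k}: a sex has fewer than {min_cells} "
                          "cells; skipped")
            continue
        A, B = expr[male], expr[fem]
        nonzero = (detected[in_k].sum(axis=0) > 0)
        cols = np.where(nonzero)[0]
        if len(cols) == 0:
            continue
        if male.sum() <= EXACT_MAX_N and fem.sum() <= EXACT_MAX_N:
            p = np.array([wilcoxon_exact_p(A[:, j], B[:, j]) for j in cols])
        else:
            p = _rank_test_vectorized(A[:, cols], B[:, cols])
        m = len(cols)
        p_adj = np.minimum(p * m, 1.0)
        det_m = detected[male].mean(axis=0)
        det_f = detected[fem].mean(axis=0)
        mean_m = cp10k[male].mean(axis=0)
        mean_f = cp10k[fem].mean(axis=0)
        for j, gi in enumerate(cols):
            if p_adj[j] >= alpha:
                continue
            ratio = (mean_m[gi] + 1.0) / (mean_f[gi] + 1.0)
            if (det_m[gi] >= tau_hi and det_f[gi] <= tau_lo) or \
                    (det_f[gi] >= tau_hi and det_m[gi] <= tau_lo):
                verdict = "sex_specific"
            elif ratio >= fold_thr or ratio <= 1.0 / fold_thr:
                verdict = "fold_different"
            else:
                verdict = "pattern_equivalent"
            records.append((genes[gi], k, float(p[j]), float(p_adj[j]),
                            float(np.log2(ratio)), float(det_m[gi]),
                            float(det_f[gi]), verdict))
    return pd.DataFrame(records, columns=["gene", "cluster", "p", "p_adj",
                                          "log2_ratio_MF", "det_male",
                                          "det_female", "verdict"])


# ---------------------------------------------------------------------------
# timepoint composition and aging depth

def timepoint_mixing(labels: Sequence, timepoint: Sequence) -> pd.DataFrame:
    """Per-cluster normalized timepoint entropy and composition chi-square.

    H_norm is the Shannon entropy of the within-cluster timepoint
    composition divided by the entropy of the global composition; 1 means
    the cluster mirrors the global mix, 0 means a single-timepoint cluster.
    """
    labels = np.asarray(labels, dtype=object)
    timepoint = np.asarray(timepoint, dtype=object)
    tps = pd.unique(timepoint)
    if len(tps) < 2:
        raise ValueError("need at least two timepoints")
    global_counts = pd.Series(timepoint).value_counts().reindex(tps).to_numpy()
    global_p = global_counts / global_counts.sum()
    h_global = float(stats.entropy(global_p))
    rows = []
    for k in pd.unique(labels):
        in_k = timepoint[labels == k]
        counts = pd.Series(in_k).value_counts().reindex(tps).fillna(0).to_numpy()
        p_vec = counts / counts.sum()
        h = float(stats.entropy(p_vec[p_vec > 0]))
        h_norm = h / h_global if h_global > 0 else np.nan
        expected = counts.sum() * global_p
        chi_p = float(stats.chisquare(counts, expected).pvalue) \
            if (expected > 0).all() else np.nan
        rows.append((k, int(counts.sum()), h_norm, chi_p,
                     *[int(c) for c in counts]))
    cols = ["cluster", "n_cells", "h_norm", "chi2_p"] + [str(t) for t in tps]
    return pd.DataFrame(rows, columns=cols).set_index("cluster")


def aging_trend(metrics: pd.DataFrame, timepoint: Sequence,
                order: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-timepoint median genes/cell and molecules/cell with a trend flag.

    ``decreasing`` on the result (attrs) is True when both medians are
    non-increasing across the ordered timepoints; undefined (None) with a
    single timepoint.
    """
    timepoint = np.asarray(timepoint, dtype=object)
    tps = list(order) if order is not None else list(pd.unique(timepoint))
    rows = []
    for t in tps:
        sub = metrics[timepoint == t]
        if len(sub) == 0:
            raise ValueError(f"no cells for timepoint {t!r}")
        rows.append((t, len(sub), float(sub["n_genes"].median()),
                     float(sub["total_counts"].median())))
    out = pd.DataFrame(rows, columns=["timepoint", "n_cells",
                                      "median_genes", "median_counts"]
                       ).set_index("timepoint")
    if len(tps) < 2:
        out.attrs["decreasing"] = None
    else:
        g = out["median_genes"].to_numpy()
        c = out["median_counts"].to_numpy()
        out.attrs["decreasing"] = bool(np.all(np.diff(g) <= 0)
                                       and np.all(np.diff(c) <= 0))
    return out


# ---------------------------------------------------------------------------
# pale:yellow ratio statistics

@dataclass
class RatioTestResult:
    """Exact binomial test of a pale fraction against an expectation p0."""

    n_pale: int
    n_yellow: int
    p0: float
    pale_fraction: float
    p_value: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {"n_pale": self.n_pale, "n_yellow": self.n_yellow,
                "p0": self.p0, "pale_fraction": self.pale_fraction,
                "p_value": self.p_value,
                "ci95": [self.ci_low, self.ci_high]}


def ratio_test_binomial(n_pale: int, n_yellow: int,
                        p0: float = 0.30) -> RatioTestResult:
    """Two-sided exact binomial test (minimum-likelihood method) of the
    pale fraction against ``p0``, with a 95% Clopper-Pearson interval."""
    if n_pale < 0 or n_yellow < 0:
        raise ValueError("counts must be non-negative")
    n = n_pale + n_yellow
    if n < 1:
        raise ValueError("need at least one cell")
    res = stats.binomtest(n_pale, n, p0, alternative="two-sided")
    ci = res.proportion_ci(confidence_level=0.95, method="exact")
    return RatioTestResult(n_pale, n_yellow, p0, n_pale / n,
                           float(res.pvalue), float(ci.low), float(ci.high))
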