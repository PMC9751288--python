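"""Normalization, HVG selection, PCA, SNN graph, Leiden communities,
2-D embedding and marker-panel cluster annotation.

This is the Seurat-style workflow reimplemented: log CP10K normalization for
expression values, highly variable genes by standardized variance against a
mean-variance trend, PCA on scaled residuals, a shared-nearest-neighbour
graph with Jaccard weights, Leiden community detection and a UMAP embedding
used for reporting only.

PCA scaling deserves a note.  The default scales each HVG by its
mean-variance-trend standard deviation (a negative-binomial Pearson
residual, overdispersion 1/theta), *without* forcing unit variance, so that
genes with strong bimodal structure — the opsins — dominate the leading
components exactly as they do under an SCTransform workflow.  A classic
per-gene z-score (which equalizes every gene's weight and therefore buries
single-gene subtype structure below the random-matrix noise floor) is
available as ``scale="zscore"``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .iocore import CountMatrix, PipelineConfig

# ---------------------------------------------------------------------------
# default marker panels (gene symbols) for cluster annotation

DEFAULT_PANELS: dict[str, dict[str, list[str]]] = {
    "R1-6": {"markers": ["ninaE"],
             "forbidden": ["Rh3", "Rh4", "Rh5", "Rh6"]},
    "R7": {"markers": ["Rh3", "Rh4", "pros"],
           "forbidden": ["ninaE", "Rh5", "Rh6"]},
    "R8": {"markers": ["Rh5", "Rh6", "sens"],
           "forbidden": ["ninaE", "Rh3", "Rh4"]},
    "cone": {"markers": ["ct", "Crys"],
             "forbidden": ["ninaE", "Rh3", "Rh4", "Rh5", "Rh6"]},
    "pigment1": {"markers": ["wrapper", "Pdh"],
                 "forbidden": ["ninaE", "Rh3", "Rh4", "Rh5", "Rh6"]},
    "pigment23": {"markers": ["santa-maria", "w", "Pdh"],
                  "forbidden": ["ninaE", "Rh3", "Rh4", "Rh5", "Rh6"]},
}


@dataclass
class SNNGraph:
    """Undirected shared-nearest-neighbour graph (Jaccard weights in (0, 1])."""

    n_vertices: int
    edges: np.ndarray      # (m, 2) int
    weights: np.ndarray    # (m,) float

    def to_igraph(self) -> igraph.Graph:
        g = igraph.Graph(n=self.n_vertices,
                         edges=[tuple(e) for e in self.edges])
        g.es["weight"] = list(self.weights)
        return g


@dataclass
class ClusteringResult:
    """Everything one clustering run produces."""

    expr: np.ndarray                  # log CP10K, cells x genes
    hvgs: np.ndarray                  # column indices, ranked
    pca: np.ndarray                   # cells x n_dims scores
    explained_variance: np.ndarray
    graph: SNNGraph
    labels: np.ndarray                # per-cell community id (int)
    embedding: np.ndarray | None      # cells x 2, reporting only
    annotation: pd.DataFrame | None   # per cluster: type, subtype, score, flags
    cell_types: np.ndarray | None = None   # per-cell annotated type

    def type_of(self, cluster: int) -> str:
        return str(self.annotation.loc[cluster, "type"])


# ---------------------------------------------------------------------------
# normalization

def normalize_log_cp10k(matrix: CountMatrix | np.ndarray) -> np.ndarray:
    """y = ln(1 + 1e4 * x / N_c); all-zero cells give all-zero rows (warned)."""
    X = matrix.densify() if isinstance(matrix, CountMatrix) else np.asarray(
        matrix, dtype=float)
    if X.size and X.min() < 0:
        raise ValueError("counts must be non-negative")
    N = X.sum(axis=1, keepdims=True)
    if np.any(N == 0):
        warnings.warn(f"{int((N == 0).sum())} all-zero cells in normalization")
    return np.log1p(1e4 * X / np.maximum(N, 1.0))


# ---------------------------------------------------------------------------
# highly variable genes

def _variance_trend(mean: np.ndarray, var: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Degree-2 polynomial fit of log10 variance on log10 mean.

    Returns (fitted variance per gene, mask of fit-informative genes).
    """
    ok = (mean > 0) & (var > 0)
    if ok.sum() < 3:
        raise ValueError("too few informative genes for a variance trend")
    coef = np.polyfit(np.log10(mean[ok]), np.log10(var[ok]), deg=2)
    with np.errstate(divide="ignore"):
        vhat = 10.0 ** np.polyval(coef, np.log10(np.maximum(mean, 1e-12)))
    return vhat, ok


def select_hvgs(matrix: CountMatrix | np.ndarray, n_hvg: int) -> np.ndarray:
    """Rank genes by standardized variance against the mean-variance trend.

    Counts are standardized per gene by the trend standard deviation,
    clipped at sqrt(n_cells), and ranked by the variance of the clipped
    values; constant genes are never selected.  Ties break by gene index.
    """
    X = matrix.densify().astype(float) if isinstance(matrix, CountMatrix) \
        else np.asarray(matrix, dtype=float)
    n = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    vhat, ok = _variance_trend(mean, var)
    clip = np.sqrt(max(n, 1))
    Z = (X - mean) / np.maximum(np.sqrt(vhat), 1e-12)
    np.clip(Z, -clip, clip, out=Z)
    sv = Z.var(axis=0)
    sv[~ok] = -np.inf
    n_informative = int(ok.sum())
    if n_informative < n_hvg:
        warnings.warn(f"only {n_informative} informative genes < n_hvg={n_hvg}")
        n_hvg = n_informative
    order = np.lexsort((np.arange(len(sv)), -sv))
    return order[:n_hvg]


# ---------------------------------------------------------------------------
# PCA

def _pearson_residuals(X: np.ndarray, theta: float) -> np.ndarray:
    N = X.sum(axis=1, keepdims=True)
    mu = N * (X.sum(axis=0, keepdims=True) / max(X.sum(), 1.0))
    R = (X - mu) / np.sqrt(mu + mu ** 2 / theta + 1e-12)
    clip = np.sqrt(max(X.shape[0], 1))
    return np.clip(R, -clip, clip)


def compute_pca(values: CountMatrix | np.ndarray,
                hvgs: np.ndarray | None = None, n_dims: int = 50,
                scale: str = "pearson", pearson_theta: float = 10.0,
                seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA scores on scaled HVG data.

    ``scale='pearson'`` (default) expects raw counts and scales by the NB
    Pearson-residual denominator; ``scale='zscore'`` z-scores each gene
    (clipped at +-10); ``scale='none'`` decomposes the input as is.  The
    sign of each component is fixed so its largest-magnitude loading is
    positive.  Returns (scores, loadings, explained variance ratio).
    """
    X = values.densify().astype(float) if isinstance(values, CountMatrix) \
        else np.asarray(values, dtype=float)
    if hvgs is not None:
        Xfull = X
        X = X[:, np.asarray(hvgs, dtype=int)]
    n, g = X.shape
    if g == 0:
        raise ValueError("no genes to decompose")
    if scale == "pearson":
        if hvgs is not None:
            # residual means use full-matrix library sizes
            N = Xfull.sum(axis=1, keepdims=True)
            mu = N * (X.sum(axis=0, keepdims=True) / max(Xfull.sum(), 1.0))
            S = (X - mu) / np.sqrt(mu + mu ** 2 / pearson_theta + 1e-12)
            S = np.clip(S, -np.sqrt(n), np.sqrt(n))
        else:
            S = _pearson_residuals(X, pearson_theta)
    elif scale == "zscore":
        sd = X.std(axis=0)
        S = (X - X.mean(axis=0)) / np.maximum(sd, 1e-12)
        S = np.clip(S, -10.0, 10.0)
    elif scale == "none":
        S = X.copy()
    else:
        raise ValueError(f"unknown scale {scale!r}")
    S = S - S.mean(axis=0)
    max_dims = min(n, S.shape[1])
    if n_dims > max_dims:
        warnings.warn(f"n_dims={n_dims} reduced to {max_dims}")
        n_dims = max_dims
    solver = "full" if min(n, S.shape[1]) < 200 else "randomized"
    p = PCA(n_components=n_dims, svd_solver=solver, random_state=seed)
    scores = p.fit_transform(S)
    loadings = p.components_
    # sign convention: the largest-magnitude loading of each PC is positive
    for j in range(loadings.shape[0]):
        i = np.argmax(np.abs(loadings[j]))
        if loadings[j, i] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    return scores, loadings, p.explained_variance_ratio_


# ---------------------------------------------------------------------------
# SNN graph and communities

def build_snn_graph(pca: np.ndarray, k: int = 20,
                    prune: float = 1.0 / 15.0) -> SNNGraph:
    """kNN by Euclidean distance, Jaccard shared-neighbour weights, pruned.

    Neighbour sets include the cell itself (so two coincident, mutually
    nearest cells get weight 1); edges with weight <= ``prune`` are removed.
    """
    n = pca.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pca)
    _, idx = nn.kneighbors(pca)   # first column is self (or a duplicate)
    rows = np.repeat(np.arange(n), k + 1)
    A = sp.csr_matrix((np.ones(n * (k + 1)), (rows, idx.ravel())),
                      shape=(n, n))
    A = A + sp.eye(n, format="csr")   # ensure self-membership
    A.data[:] = 1.0                   # deduplicate
    shared = (A @ A.T).tocoo()
    sizes = np.asarray(A.sum(axis=1)).ravel()
    mask = shared.row < shared.col
    r, c, sh = shared.row[mask], shared.col[mask], shared.data[mask]
    union = sizes[r] + sizes[c] - sh
    w = sh / union
    keep = w > prune
    edges = np.stack([r[keep], c[keep]], axis=1)
    weights = w[keep]
    if len(edges) == 0:
        raise ValueError("SNN graph has no edges; increase k")
    return SNNGraph(n, edges, weights)


def detect_communities(graph: SNNGraph, resolution: float = 0.8,
                       seed: int = 0) -> np.ndarray:
    """Leiden communities (RB-configuration modularity) on the SNN graph."""
    g = graph.to_igraph()
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=int(seed),
        n_iterations=2)
    return np.asarray(part.membership, dtype=int)


# ---------------------------------------------------------------------------
# embedding (reporting only)

def embed_2d(pca: np.ndarray, seed: int = 0,
             n_neighbors: int = 15, min_dist: float = 0.3) -> np.ndarray:
    """Seeded UMAP of the PC scores; no downstream statistic depends on it."""
    import umap  # deferred: numba compilation is expensive

    n = pca.shape[0]
    if n == 0:
        return np.zeros((0, 2))
    nb = int(min(n_neighbors, max(n - 1, 2)))
    init = "spectral" if n > 10 else "random"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=nb, min_dist=min_dist,
                            random_state=int(seed), init=init)
        return np.asarray(reducer.fit_transform(pca), dtype=float)


# ---------------------------------------------------------------------------
# annotation

def _detection_by_cluster(X: np.ndarray, labels: np.ndarray,
                          col: int) -> dict:
    det = {}
    for k in np.unique(labels):
        det[k] = float((X[labels == k, col] > 0).mean())
    return det


def annotate_clusters(expr: np.ndarray, labels: Sequence,
                      gene_symbols: Sequence[str],
                      panels: Mapping[str, Mapping[str, Sequence[str]]]
                      | None = None,
                      counts: np.ndarray | None = None) -> pd.DataFrame:
    """Assign a cell type (and photoreceptor subtype) to every cluster.

    Per cluster and candidate type, the score is the mean over the panel's
    marker genes of the cluster-mean expression z-scored across clusters;
    the argmax type is assigned ("ambiguous" on ties).  R7/R8 clusters get a
    pale/yellow subtype from the dominant opsin, a dorsal-third flag when
    both R7 opsins are detected in >= 50% of cells, and a dorsal-rim (DRA)
    flag when Rh3 and hth are detected with all other opsins rare.
    """
    panels = DEFAULT_PANELS if panels is None else panels
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    sym_idx = {s: i for i, s in enumerate(gene_symbols)}
    clusters = np.unique(labels)
    # cluster x gene mean expression
    means = np.stack([expr[labels == k].mean(axis=0) for k in clusters])
    mu = means.mean(axis=0)
    sd = means.std(axis=0)
    z = (means - mu) / np.maximum(sd, 1e-12)

    det_cache: dict[str, dict] = {}

    def det(gene, k):
        if gene not in sym_idx:
            return 0.0
        if gene not in det_cache:
            X = expr if counts is None else counts
            det_cache[gene] = _detection_by_cluster(
                np.asarray(X), labels, sym_idx[gene])
        return det_cache[gene][k]

    rows = []
    for ki, k in enumerate(clusters):
        scores = {}
        for ty, panel in panels.items():
            cols = []
            for gsym in panel["markers"]:
                if gsym not in sym_idx:
                    warnings.warn(f"panel gene {gsym!r} absent; skipped")
                    continue
                cols.append(sym_idx[gsym])
            if not cols:
                continue
            scores[ty] = float(np.mean(z[ki, cols]))
        if not scores:
            rows.append((k, "ambiguous", "", np.nan, False, False))
            continue
        best = max(scores.values())
        winners = [t for t, v in scores.items() if v == best]
        ty = winners[0] if len(winners) == 1 else "ambiguous"
        subtype, dorsal3, dra = "", False, False
        if ty in ("R7", "R8"):
            pale_gene, yellow_gene = (("Rh3", "Rh4") if ty == "R7"
                                      else ("Rh5", "Rh6"))
            mp = means[ki, sym_idx[pale_gene]] if pale_gene in sym_idx else 0
            my = means[ki, sym_idx[yellow_gene]] if yellow_gene in sym_idx else 0
            subtype = "pale" if mp > my else "yellow"
            if ty == "R7" and det("Rh3", k) >= 0.5 and det("Rh4", k) >= 0.5:
                dorsal3 = True
            if (det("Rh3", k) >= 0.5 and det("hth", k) >= 0.5
                    and all(det(gn, k) < 0.1 for gn in ("Rh4", "Rh5", "Rh6"))):
                dra = True
        rows.append((k, ty, subtype, best if scores else np.nan, dorsal3, dra))
    return pd.DataFrame(rows, columns=["cluster", "type", "subtype", "score",
                                       "dorsal3", "dra"]).set_index("cluster")


# ---------------------------------------------------------------------------
# convenience driver

def run_clustering(matrix: CountMatrix, config: PipelineConfig | None = None,
                   panels=None, with_embedding: bool = False,
                   seed: int | None = None) -> ClusteringResult:
    """normalize -> HVG -> PCA -> SNN -> Leiden (-> UMAP) -> annotate."""
    cfg = config or PipelineConfig()
    s = cfg.seed if seed is None else seed
    expr = normalize_log_cp10k(matrix)
    hvgs = select_hvgs(matrix, cfg.n_hvg)
    if cfg.pca_scale == "pearson":
        scores, _, evr = compute_pca(matrix, hvgs, cfg.n_dims, "pearson",
                                     cfg.pearson_theta, seed=s)
    else:
        scores, _, evr = compute_pca(expr, hvgs, cfg.n_dims, "zscore", seed=s)
    graph = build_snn_graph(scores, cfg.neighbors_k, cfg.snn_prune)
    labels = detect_communities(graph, cfg.resolution, seed=s)
    emb = embed_2d(scores, seed=s) if with_embedding else None
    counts = matrix.densify()
    ann = annotate_clusters(expr, labels, matrix.gene_symbols, panels,
                            counts=counts)
    cell_types = ann["type"].reindex(labels).to_numpy(dtype=object)
    return ClusteringResult(expr=expr, hvgs=hvgs, pca=scores,
                            explained_variance=evr, graph=graph,
                            labels=labels, embedding=emb, annotation=ann,
                            cell_types=cell_types)
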