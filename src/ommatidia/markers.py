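"""Marker-gene calling, cross-dataset intersection, the three-class
specificity screen, shared-pair markers and gene-set over-representation.

Marker calling is one-vs-rest Wilcoxon rank-sum on log CP10K expression,
gated like Seurat's FindAllMarkers (only positive markers, detection in at
least ``min_pct`` of either group, log2 fold change of at least
``logfc_threshold`` on mean-CP10K-plus-one) with Bonferroni adjustment over
the genes tested for that cluster.

"Expressed in a cluster" is operationalized as detection fraction >= tau
(default 0.10).  A candidate marker is Class 1 when expressed only in its
home cluster, Class 2 when in exactly one other, Class 3 when in two or
more others (but not all), "ubiquitous" when expressed in every evaluated
cluster, and "not_expressed" (an anomaly flag) when not expressed in its
own home cluster.
"""
from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .iocore import CountMatrix

EXACT_MAX_N = 10   # exact rank-sum enumeration when both groups are this small


# ---------------------------------------------------------------------------
# rank-sum machinery

def wilcoxon_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumeration (midranks for ties).

    Enumerates all C(n1+n2, n1) assignments of the pooled observations and
    counts those whose U statistic is at least as far from its null mean as
    the observed one.  Intended for small groups (n1, n2 <= 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    mean_u = n1 * n2 / 2.0
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    obs_dev = abs(obs_u - mean_u)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mean_u) >= obs_dev - 1e-12:
            count += 1
        total += 1
    return count / total


def _rank_test_vectorized(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Two-sided tie-corrected normal-approximation MWU per column."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(A, B, axis=0, method="asymptotic",
                                 use_continuity=True)
    return np.atleast_1d(res.pvalue)


def rank_test(x: np.ndarray, y: np.ndarray) -> float:
    """Single-gene rank-sum p: exact enumeration for small groups, else
    tie-corrected normal approximation."""
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return wilcoxon_exact_p(x, y)
    return float(_rank_test_vectorized(x[:, None], y[:, None])[0])


# ---------------------------------------------------------------------------
# marker calling

def _mean_cp10k(expr_counts: np.ndarray) -> np.ndarray:
    N = expr_counts.sum(axis=1, keepdims=True)
    return 1e4 * expr_counts / np.maximum(N, 1.0)


def log2_fold_change(mean_in: np.ndarray, mean_out: np.ndarray) -> np.ndarray:
    """log2 of (mean CP10K + 1) ratio, the Seurat-family convention."""
    return np.log2((mean_in + 1.0) / (mean_out + 1.0))


def rank_markers_wilcoxon(expr: np.ndarray, labels: Sequence,
                          counts: np.ndarray | None = None,
                          gene_symbols: Sequence[str] | None = None,
                          min_pct: float = 0.25, logfc_threshold: float = 0.25,
                          only_pos: bool = True, min_cells: int = 3
                          ) -> pd.DataFrame:
    """One-vs-rest marker table over all clusters.

    ``expr`` is log CP10K (used for the rank test); ``counts`` (raw) is used
    for mean-CP10K fold changes and detection fractions and defaults to
    ``expm1``-backtransformed expr.  Clusters with fewer than ``min_cells``
    cells are skipped with a warning.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise ValueError("marker calling needs at least two clusters")
    if counts is None:
        cp10k = np.expm1(expr)
    else:
        cp10k = _mean_cp10k(np.asarray(counts, dtype=float))
    genes = (np.asarray(gene_symbols, dtype=object) if gene_symbols is not None
             else np.array([f"g{i}" for i in range(expr.shape[1])], dtype=object))
    detected = expr > 0
    records = []
    for k in clusters:
        in_mask = labels == k
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < min_cells or n_out < min_cells:
            warnings.warn(f"cluster {k}: fewer than {min_cells} cells in a "
                          "group; skipped")
            continue
        pct_in = detected[in_mask].mean(axis=0)
        pct_out = detected[~in_mask].mean(axis=0)
        m_in = cp10k[in_mask].mean(axis=0)
        m_out = cp10k[~in_mask].mean(axis=0)
        lfc = log2_fold_change(m_in, m_out)
        testable = np.maximum(pct_in, pct_out) >= min_pct
        if only_pos:
            testable &= lfc >= logfc_threshold
        else:
            testable &= np.abs(lfc) >= logfc_threshold
        cols = np.where(testable)[0]
        if len(cols) == 0:
            continue
        A, B = expr[in_mask][:, cols], expr[~in_mask][:, cols]
        if n_in <= EXACT_MAX_N and n_out <= EXACT_MAX_N:
            p = np.array([wilcoxon_exact_p(A[:, j], B[:, j])
                          for j in range(len(cols))])
        else:
            p = _rank_test_vectorized(A, B)
        m = len(cols)
        p_adj = np.minimum(p * m, 1.0)
        for j, gi in enumerate(cols):
            records.append((genes[gi], k, float(lfc[gi]), float(pct_in[gi]),
                            float(pct_out[gi]), float(p[j]), float(p_adj[j])))
    table = pd.DataFrame(records, columns=["gene", "cluster", "log2fc",
                                           "pct_in", "pct_out", "p", "p_adj"])
    return table.sort_values(["cluster", "p", "gene"]).reset_index(drop=True)


def intersect_markers(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Genes called for the same cluster label in every table.

    Ordered per cluster by the worst (largest) p across tables.
    """
    if len(tables) < 2:
        raise ValueError("need at least two marker tables to intersect")
    all_clusters = set()
    for t in tables:
        all_clusters |= set(t["cluster"])
    rows = []
    for k in sorted(all_clusters, key=str):
        gene_sets = []
        for t in tables:
            sub = t[t["cluster"] == k]
            if sub.empty:
                warnings.warn(f"cluster {k} absent from one table; "
                              "empty intersection")
            gene_sets.append(set(sub["gene"]))
        common = set.intersection(*gene_sets) if gene_sets else set()
        for gsym in common:
            worst_p = max(float(t.loc[(t["cluster"] == k)
                                      & (t["gene"] == gsym), "p"].iloc[0])
                          for t in tables)
            rows.append((gsym, k, worst_p))
    out = pd.DataFrame(rows, columns=["gene", "cluster", "worst_p"])
    return out.sort_values(["cluster", "worst_p", "gene"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# specificity classes

CLASS_LABELS = ("1", "2", "3", "ubiquitous", "not_expressed")


def classify_specificity(expr: np.ndarray, labels: Sequence,
                         candidates: pd.DataFrame, tau: float = 0.10,
                         exclude_clusters: Sequence = (),
                         gene_symbols: Sequence[str] | None = None
                         ) -> pd.DataFrame:
    """Assign specificity class 1/2/3/ubiquitous/not_expressed per candidate.

    ``candidates`` needs columns gene and cluster (a marker table).  A gene
    is "expressed" in a cluster when its detection fraction is >= tau there;
    clusters listed in ``exclude_clusters`` are ignored (mirroring the
    exclusion of underrepresented cell types from the screen).  A
    candidate's home cluster may not be excluded.
    """
    expr = np.asarray(expr)
    labels = np.asarray(labels)
    genes = (np.asarray(gene_symbols, dtype=object) if gene_symbols is not None
             else np.array([f"g{i}" for i in range(expr.shape[1])], dtype=object))
    gidx = {s: i for i, s in enumerate(genes)}
    excluded = set(exclude_clusters)
    evaluated = [k for k in pd.unique(labels) if k not in excluded]
    det = {k: (expr[labels == k] > 0).mean(axis=0) for k in evaluated}
    rows = []
    for gsym, home in zip(candidates["gene"], candidates["cluster"]):
        if home in excluded:
            raise ValueError(f"home cluster {home!r} is excluded from the screen")
        gi = gidx[gsym]
        expressed = {k for k in evaluated if det[k][gi] >= tau}
        if home not in expressed:
            cls = "not_expressed"
        elif len(expressed) == len(evaluated):
            cls = "ubiquitous"
        else:
            n_other = len(expressed) - 1
            cls = "1" if n_other == 0 else ("2" if n_other == 1 else "3")
        rows.append((gsym, home, cls, len(expressed)))
    return pd.DataFrame(rows, columns=["gene", "cluster", "specificity_class",
                                       "n_expressed_clusters"])


def find_shared_pair_markers(expr: np.ndarray, labels: Sequence,
                             pair: tuple = ("R7", "R8"), tau: float = 0.10,
                             exclude_clusters: Sequence = (),
                             gene_symbols: Sequence[str] | None = None
                             ) -> list[str]:
    """Genes detected >= tau in both members of ``pair`` and < tau elsewhere."""
    expr = np.asarray(expr)
    labels = np.asarray(labels)
    present = set(pd.unique(labels))
    for m in pair:
        if m not in present:
            raise ValueError(f"pair member {m!r} missing from labels")
    if tau <= 0:
        warnings.warn("tau <= 0 returns every gene with any count in the pair")
    genes = (np.asarray(gene_symbols, dtype=object) if gene_symbols is not None
             else np.array([f"g{i}" for i in range(expr.shape[1])], dtype=object))
    excluded = set(exclude_clusters)
    evaluated = [k for k in pd.unique(labels) if k not in excluded]
    det = {k: (expr[labels == k] > 0).mean(axis=0) for k in evaluated}
    others = [k for k in evaluated if k not in pair]
    out = []
    for gi, gsym in enumerate(genes):
        if all(det[m][gi] >= tau for m in pair) and \
                all(det[k][gi] < tau for k in others):
            out.append(str(gsym))
    return out


# ---------------------------------------------------------------------------
# over-representation

def hypergeom_enrichment(marker_list: Sequence[str],
                         gene_sets: Mapping[str, Sequence[str]],
                         universe: Sequence[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation with BH q-values.

    For each set: overlap with ``marker_list``, fold enrichment
    (observed/expected overlap) and p = P[X >= overlap] for X hypergeometric
    over the universe.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uset = set(universe)
    mset = set(marker_list) & uset
    if len(mset) < len(set(marker_list)):
        warnings.warn("marker genes outside the universe were ignored")
    M, n_draw = len(universe), len(mset)
    rows = []
    for name, members in gene_sets.items():
        s = set(members) & uset
        k = len(s & mset)
        expected = n_draw * len(s) / M
        p = float(stats.hypergeom.sf(k - 1, M, len(s), n_draw)) if s else 1.0
        fold = (k / expected) if expected > 0 else np.nan
        rows.append((name, k, len(s), expected, fold, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                        "expected", "fold_enrichment", "p"])
    table["q"] = stats.false_discovery_control(table["p"], method="bh") \
        if len(table) else []
    return table.sort_values(["p", "set"]).reset_index(drop=True)
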