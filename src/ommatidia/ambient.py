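"""Cluster-aware ambient-RNA ("soup") estimation and correction.

Droplet suspensions carry cell-free transcripts that contaminate every
droplet in proportion to a shared soup profile; in eye tissue the soup is
dominated by ninaE, the most abundant transcript.  The soup profile is
estimated as the dataset-wide expression profile, and the per-cluster
contamination fraction rho from "forbidden" genes — genes that the cluster's
cell type cannot transcribe (opsin exclusivity: a pale R8 makes no Rh6), so
that every observed forbidden count must be soup:

    rho_k = sum_c sum_{g in F_k} x_cg  /  ( sum_c N_c * sum_{g in F_k} s_g )

Correction removes the expected soup per (cluster, gene), allocated to the
cluster's cells in proportion to their observed counts; entries never
increase and stay integral.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .iocore import CountMatrix

RHO_CLIP = 0.5


@dataclass
class SoupProfile:
    """Per-gene soup fractions s_g (non-negative, summing to 1)."""

    s: np.ndarray
    gene_symbols: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.s.min() < 0 or abs(self.s.sum() - 1.0) > 1e-9:
            raise ValueError("soup profile must be non-negative and sum to 1")


@dataclass
class ContaminationEstimate:
    """Per-cluster contamination fraction rho with rough standard errors.

    ``table`` columns: rho, se, n_cells, forbidden_counts, usable.  Clusters
    whose forbidden genes carry no soup mass are flagged unusable rather
    than silently reported as zero.
    """

    table: pd.DataFrame

    def rho_for(self, cluster) -> float:
        return float(self.table.loc[cluster, "rho"])


def estimate_soup_profile(matrix: CountMatrix) -> SoupProfile:
    """Soup profile = column sums / grand total of the (raw) count matrix."""
    colsum = np.asarray(matrix.X.sum(axis=0)).ravel().astype(float)
    total = colsum.sum()
    if total <= 0:
        raise ValueError("cannot estimate a soup profile from an all-zero matrix")
    return SoupProfile(colsum / total, matrix.gene_symbols.copy())


def estimate_contamination(matrix: CountMatrix, labels: Sequence,
                           forbidden: Mapping[object, Sequence[str]],
                           soup: SoupProfile | None = None
                           ) -> ContaminationEstimate:
    """Estimate rho per cluster from forbidden-gene counts.

    ``forbidden`` maps cluster label -> gene symbols the cluster's cell type
    does not transcribe.  rho is clipped to [0, 0.5]; exceeding the clip
    warns (it indicates either a mis-specified forbidden set or pathological
    contamination).
    """
    if soup is None:
        soup = estimate_soup_profile(matrix)
    labels = np.asarray(labels, dtype=object)
    N = matrix.library_sizes().astype(float)
    rows = []
    for k in pd.unique(labels):
        cells = np.where(labels == k)[0]
        genes = list(forbidden.get(k, []))
        present = [g for g in genes if g in set(matrix.gene_symbols)]
        if len(present) < len(genes):
            warnings.warn(f"cluster {k}: forbidden genes absent from matrix: "
                          f"{sorted(set(genes) - set(present))}")
        if not present:
            rows.append((k, np.nan, np.nan, len(cells), 0.0, False))
            continue
        idx = matrix.gene_index(present)
        s_mass = float(soup.s[idx].sum())
        count = float(matrix.X[np.ix_(cells, idx)].sum())
        denom = float(N[cells].sum()) * s_mass
        if denom <= 0:
            rows.append((k, np.nan, np.nan, len(cells), count, False))
            continue
        rho_raw = count / denom
        rho = min(max(rho_raw, 0.0), RHO_CLIP)
        if rho_raw > RHO_CLIP:
            warnings.warn(
                f"cluster {k}: raw contamination estimate {rho_raw:.3f} "
                f"clipped at {RHO_CLIP}")
        se = np.sqrt(max(count, 1.0)) / denom   # Poisson-count approximation
        rows.append((k, rho, se, len(cells), count, True))
    table = pd.DataFrame(rows, columns=["cluster", "rho", "se", "n_cells",
                                        "forbidden_counts", "usable"]
                         ).set_index("cluster")
    return ContaminationEstimate(table)


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lo = np.floor(x)
    return (lo + (rng.random(x.shape) < (x - lo))).astype(np.int64)


def correct_ambient(matrix: CountMatrix, soup: SoupProfile,
                    estimate: ContaminationEstimate, labels: Sequence,
                    seed: int = 0) -> CountMatrix:
    """Subtract expected soup counts; cluster-level, integral, never negative.

    For cluster k and gene g the expected soup is
    ``E_kg = rho_k * (sum of cluster library sizes) * s_g``; the removed
    amount is ``min(observed, stochastic_round(E_kg))``, distributed over
    the cluster's cells by a multivariate hypergeometric draw weighted by
    each cell's observed counts.  Clusters flagged unusable are left
    untouched.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    X = matrix.X.tocsc().astype(np.int64)
    out = X.toarray()
    N = matrix.library_sizes().astype(float)
    for k, row in estimate.table.iterrows():
        if not row["usable"] or not np.isfinite(row["rho"]) or row["rho"] <= 0:
            continue
        cells = np.where(labels == k)[0]
        if len(cells) == 0:
            continue
        expected = row["rho"] * N[cells].sum() * soup.s
        target = _stochastic_round(expected, rng)
        observed = out[cells].sum(axis=0)
        remove = np.minimum(observed, target)
        for g in np.where(remove > 0)[0]:
            col = out[cells, g]
            r = int(remove[g])
            if col.sum() <= r:
                out[cells, g] = 0
                continue
            taken = rng.multivariate_hypergeometric(col, r)
            out[cells, g] = col - taken
    return CountMatrix(sp.csr_matrix(out), matrix.barcodes.copy(),
                       matrix.gene_ids.copy(), matrix.gene_symbols.copy())
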