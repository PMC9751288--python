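"""Count-matrix container, 10x-style MatrixMarket I/O, pipeline configuration and reports.

The on-disk layout mirrors the 10x Genomics convention: a directory with
``matrix.mtx`` (MatrixMarket coordinate integer, genes x cells), a
``features.tsv`` with gene id / gene symbol columns and a ``barcodes.tsv``
with one droplet barcode per line.  In memory everything is oriented
cells x genes.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class ParseError(ValueError):
    """Raised when an on-disk matrix or configuration violates its contract."""


def _check_unique(values: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for v in values:
        if v in seen:
            dups.append(v)
        seen[v] = 1
    if dups:
        raise ParseError(f"duplicate {what}: {sorted(set(dups))[:10]}")


@dataclass
class CountMatrix:
    """Sparse non-negative integer cells x genes matrix with identifiers.

    Attributes
    ----------
    X : scipy.sparse.csr_matrix
        Integer counts, one row per cell.
    barcodes : np.ndarray of str
        Unique droplet barcodes (row labels).
    gene_ids, gene_symbols : np.ndarray of str
        Column labels; ids are unique, symbols are the working names used
        throughout the pipeline (opsins, panel genes, ...).
    """

    X: sp.csr_matrix
    barcodes: np.ndarray
    gene_ids: np.ndarray
    gene_symbols: np.ndarray

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        n, g = self.X.shape
        if n != len(self.barcodes):
            raise ParseError(
                f"matrix has {n} rows but {len(self.barcodes)} barcodes")
        if g != len(self.gene_ids) or g != len(self.gene_symbols):
            raise ParseError(
                f"matrix has {g} columns but {len(self.gene_ids)} gene ids")
        _check_unique(list(self.barcodes), "barcodes")
        _check_unique(list(self.gene_ids), "gene ids")
        if self.X.nnz and self.X.data.min() < 0:
            raise ParseError("negative counts are not allowed")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def gene_index(self, symbols: Iterable[str]) -> np.ndarray:
        """Column indices for gene symbols; raises KeyError naming the absentee."""
        lut = {s: i for i, s in enumerate(self.gene_symbols)}
        idx = []
        for s in symbols:
            if s not in lut:
                raise KeyError(f"gene symbol not present: {s!r}")
            idx.append(lut[s])
        return np.asarray(idx, dtype=int)

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1)).ravel()

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.where(idx)[0]
        return CountMatrix(self.X[idx], self.barcodes[idx],
                           self.gene_ids, self.gene_symbols)

    def subset_genes(self, keep_idx) -> "CountMatrix":
        keep_idx = np.asarray(keep_idx, dtype=int)
        return CountMatrix(self.X[:, keep_idx], self.barcodes,
                           self.gene_ids[keep_idx], self.gene_symbols[keep_idx])

    def densify(self) -> np.ndarray:
        return np.asarray(self.X.todense())


def write_counts_mtx(matrix: CountMatrix, directory: str | Path) -> None:
    """Write matrix.mtx (genes x cells, coordinate integer), features.tsv, barcodes.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = matrix.X.data
    if data.size and not np.allclose(data, np.round(data)):
        raise ValueError("refusing to write non-integer counts as integer MatrixMarket")
    coo = sp.coo_matrix(matrix.X.T.astype(np.int64))  # genes x cells, 10x layout
    scipy.io.mmwrite(str(directory / "matrix.mtx"), coo, field="integer")
    feats = pd.DataFrame({
        "id": matrix.gene_ids,
        "symbol": matrix.gene_symbols,
        "type": "Gene Expression",
    })
    feats.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(matrix.barcodes).to_csv(
        directory / "barcodes.tsv", header=False, index=False)


def read_counts_mtx(directory: str | Path) -> CountMatrix:
    """Read a 10x-style directory, accepting both genes x cells and cells x genes.

    Orientation is resolved from the MatrixMarket header against the lengths
    of features.tsv and barcodes.tsv; the result is always cells x genes.
    """
    directory = Path(directory)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (directory / name).exists():
            raise ParseError(f"missing {name} in {directory}")
    feats = pd.read_csv(directory / "features.tsv", sep="\t", header=None,
                        dtype=str)
    if feats.shape[1] < 2:
        feats[1] = feats[0]
    gene_ids = feats[0].to_numpy(dtype=object)
    gene_symbols = feats[1].to_numpy(dtype=object)
    with open(directory / "barcodes.tsv") as fh:
        barcodes = np.array([ln.strip() for ln in fh if ln.strip()], dtype=object)
    M = scipy.io.mmread(str(directory / "matrix.mtx"))
    M = sp.csr_matrix(M)
    n_genes, n_cells = len(gene_ids), len(barcodes)
    if M.shape == (n_genes, n_cells):
        # 10x layout; also the preferred reading when the matrix is square
        M = M.T.tocsr()
    elif M.shape == (n_cells, n_genes):
        pass
    else:
        raise ParseError(
            f"matrix shape {M.shape} matches neither (genes={n_genes}, "
            f"cells={n_cells}) nor its transpose")
    if M.nnz and M.data.min() < 0:
        raise ParseError("negative values in matrix.mtx")
    return CountMatrix(M.astype(np.int64), barcodes, gene_ids, gene_symbols)


# ---------------------------------------------------------------------------
# pipeline configuration

#: per-dataset thresholds used in the published analysis:
#: (mito_max, gene_min, gene_max, n_hvg) for 1D male, 3D male, 7D male, 1D female
PUBLISHED_THRESHOLDS = {
    "1D_male": (0.20, 200, 3500, 3500),
    "3D_male": (0.25, 200, 2800, 2800),
    "7D_male": (0.18, 200, 2700, 2700),
    "1D_female": (0.25, 200, 4000, 4000),
}


@dataclass
class PipelineConfig:
    """Tunable parameters of the analysis pipeline.

    Defaults follow the Seurat-workflow conventions the analysis assumes:
    50 principal components, k=20 shared-nearest-neighbour graph pruned at
    Jaccard 1/15, Leiden resolution 0.8, marker calling with min.pct 0.25
    and log2 fold-change threshold 0.25, detection threshold tau=0.10 for
    the specificity classes.
    """

    mito_max: float = 0.20
    gene_min: int = 200
    gene_max: int = 3500
    n_hvg: int = 1000
    n_dims: int = 50
    neighbors_k: int = 20
    snn_prune: float = 1.0 / 15.0
    resolution: float = 0.8
    pca_scale: str = "pearson"   # "pearson" (NB residuals) or "zscore"
    pearson_theta: float = 10.0  # NB size parameter; overdispersion 1/theta
    min_pct: float = 0.25
    logfc_threshold: float = 0.25
    tau: float = 0.10
    noneye_frac_threshold: float = 0.5
    marker_panel: str | None = None
    seed: int = 0
    run_embedding: bool = True
    run_ablation: bool = True
    run_compare: bool = True

    def validate(self) -> None:
        if not (0 < self.mito_max <= 1):
            raise ValueError(f"mito_max must be in (0, 1], got {self.mito_max}")
        if self.gene_min >= self.gene_max:
            raise ValueError(
                f"gene_min ({self.gene_min}) must be < gene_max ({self.gene_max})")
        if self.n_dims < 2:
            raise ValueError(f"n_dims must be >= 2, got {self.n_dims}")
        if self.pca_scale not in ("pearson", "zscore"):
            raise ValueError(f"unknown pca_scale {self.pca_scale!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a JSON pipeline config; unknown keys warn, invariants raise."""
    path = Path(path)
    text = path.read_text().strip()
    raw: Mapping = json.loads(text) if text else {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# report

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


REPORT_SECTIONS = ("qc", "ambient", "clusters", "markers", "ablation", "compare",
                   "parameters", "seeds")


def write_report(results: Mapping, path: str | Path) -> dict:
    """Write the pipeline report as schema-stable JSON; returns the document."""
    doc = {k: _jsonable(results.get(k, {})) for k in REPORT_SECTIONS}
    for k in results:
        if k not in REPORT_SECTIONS:
            doc[k] = _jsonable(results[k])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return doc


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
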