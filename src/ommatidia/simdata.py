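"""Synthetic ommatidial-retina scRNA-seq generator.

Emulates the statistical structure of adult fly-eye droplet scRNA-seq data:
six major cell types in anatomically expected proportions, photoreceptor
subtypes defined by mutually exclusive Rhodopsin expression (ninaE in R1-6;
Rh3 xor Rh4 in R7 with dorsal-third co-expression; Rh5 xor Rh6 in R8; dorsal
rim area R7/R8 expressing Rh3 plus hth), a ~30:70 pale:yellow subtype ratio,
a ninaE-dominated ambient-RNA "soup", mitochondrial reads, doublets and a
per-timepoint sequencing-depth decline.  Ground truth is returned for every
planted feature so each pipeline stage can be scored.

The count model is negative binomial (gamma-Poisson) with per-gene
dispersion drawn from a gamma prior and a log-normal per-cell size factor.
Gene-gene correlation beyond shared cell-type programs is not modelled.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import json
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .iocore import CountMatrix, write_counts_mtx

# cell-type labels used throughout the package
R16, R7, R8 = "R1-6", "R7", "R8"
CONE, PIG1, PIG23, NONEYE = "cone", "pigment1", "pigment23", "noneye"
EYE_TYPES = (R16, R7, R8, CONE, PIG1, PIG23)

#: anatomically expected per-ommatidium composition (percent; bristle cells
#: not counted, hence the /90 renormalization), scaled to leave room for a
#: 3% non-eye (brain neuron / glia) contaminant fraction.
_EXPECTED_PCT = {R16: 30.0, R7: 5.0, R8: 5.0, CONE: 20.0, PIG1: 10.0, PIG23: 20.0}
DEFAULT_PROPORTIONS = {t: (p / 90.0) * 0.97 for t, p in _EXPECTED_PCT.items()}
DEFAULT_PROPORTIONS[NONEYE] = 0.03

OPSINS = ("ninaE", "Rh3", "Rh4", "Rh5", "Rh6")
PANEL_GENES = ("sens", "pros", "ct", "Crys", "w", "Pdh", "santa-maria",
               "wrapper", "hth", "Skeletor", "fne", "moody", "repo")
#: photoreceptor-shared high-expression program (phototransduction cascade and
#: structural genes expressed in all R1-8 photoreceptors)
PR_PROGRAM_GENES = ("trp", "trpl", "Arr1", "Arr2", "ninaC", "inaC", "inaD",
                    "norpA", "Galpha49B", "Gbeta76C", "chp", "oc", "Zasp66",
                    "ninaA", "retinin")
MITO_GENES = ("mt:CoI", "mt:CoII", "mt:CoIII", "mt:ATPase6", "mt:Cyt-b",
              "mt:ND1", "mt:ND2", "mt:ND4", "mt:ND5", "mt:srRNA")

NONEYE_MARKERS = ("fne", "moody", "repo")


class SimConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass
class SimConfig:
    """Generator configuration.

    ``proportions`` must sum to 1.  ``depth_decline`` gives a library-size
    multiplier per entry of ``timepoints`` (the third timepoint defaults to
    0.6, emulating the depth decline seen in aged animals).
    """

    n_cells: int = 5000
    proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    pale_prob: float = 0.30
    dorsal3_frac: float = 0.15
    dra_frac: float = 0.02
    n_genes: int = 2000
    n_markers_per_type: int = 20
    marker_fold: float = 8.0
    rho_mean: float = 0.05
    rho_conc: float = 50.0
    mito_frac_mean: float = 0.08
    mito_conc: float = 50.0
    doublet_rate: float = 0.01
    depth_decline: Sequence[float] = (1.0, 1.0, 0.6)
    timepoints: Sequence[str] = ("1D", "3D", "7D")
    female_frac: float = 0.0
    sex_offset: float = 0.0   # planted batch offset: log-fold shift on a random
                              # gene subset for female cells (0 = identical biology)
    seed: int = 0

    # count-model constants (documented in the methods note)
    base_log_mean: float = -1.0
    base_log_sd: float = 1.0
    marker_base_mean: float = 0.07
    marker_base_sd: float = 0.15
    opsin_mean: float = 150.0
    ninae_mean: float = 400.0
    weak_panel_mean: float = 1.0    # sens / pros ("weakly expressed")
    pr_program_mean: float = 15.0
    libsize_log_sd: float = 0.30
    disp_shape: float = 2.0
    disp_scale: float = 1.5
    disp_floor: float = 0.5

    def validate(self) -> None:
        total = float(sum(self.proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(
                f"cell-type proportions sum to {total}, expected 1")
        for name in ("pale_prob", "dorsal3_frac", "dra_frac", "rho_mean",
                     "mito_frac_mean", "female_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if self.doublet_rate >= 0.5:
            raise SimConfigError(
                f"doublet_rate {self.doublet_rate} >= 0.5 is implausible")
        if self.doublet_rate < 0:
            raise SimConfigError("doublet_rate must be >= 0")
        if self.marker_fold < 1:
            raise SimConfigError("marker_fold must be >= 1")
        if self.n_cells < 0 or self.n_genes <= 0:
            raise SimConfigError("n_cells must be >= 0 and n_genes positive")
        if len(self.depth_decline) != len(self.timepoints):
            raise SimConfigError("depth_decline must match timepoints in length")
        if any(d <= 0 or d > 1 for d in self.depth_decline):
            raise SimConfigError("depth multipliers must be in (0, 1]")


@dataclass
class GroundTruth:
    """Planted truth for every cell and gene.

    ``cells``: type, subtype, timepoint, sex, rho (contamination fraction),
    doublet flag.  ``genes``: marker_of (planted cell-type program, '' if
    none), soup_frac s_g, mito flag.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def sample_cell_types(config: SimConfig, seed: int) -> pd.DataFrame:
    """Draw per-cell (type, subtype, timepoint, sex) labels.

    Types are multinomial in ``config.proportions``.  Within R7/R8 a cell is
    pale with probability ``pale_prob`` else yellow; a yellow R7 co-expresses
    both R7 opsins (dorsal-third) with probability ``dorsal3_frac``; any
    inner photoreceptor is reassigned to the dorsal-rim subtype with
    probability ``dra_frac`` (independently of the pale draw, so the
    pale:yellow ratio among non-DRA cells is exactly ``pale_prob``).
    """
    config.validate()
    rng = _rng(seed)
    types = list(config.proportions.keys())
    probs = np.array([config.proportions[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    n = config.n_cells
    t_idx = rng.choice(len(types), size=n, p=probs)
    type_lab = np.array(types, dtype=object)[t_idx]
    subtype = type_lab.astype(object).copy()

    is_r7 = type_lab == R7
    is_r8 = type_lab == R8
    pale = rng.random(n) < config.pale_prob
    d3 = rng.random(n) < config.dorsal3_frac
    dra = rng.random(n) < config.dra_frac

    subtype[is_r7 & pale] = "R7-pale"
    subtype[is_r7 & ~pale & d3] = "R7-dorsal3"
    subtype[is_r7 & ~pale & ~d3] = "R7-yellow"
    subtype[is_r8 & pale] = "R8-pale"
    subtype[is_r8 & ~pale] = "R8-yellow"
    subtype[(is_r7 | is_r8) & dra] = "DRA"

    tp = np.array(config.timepoints, dtype=object)[
        rng.integers(0, len(config.timepoints), size=n)]
    sex = np.where(rng.random(n) < config.female_frac, "F", "M").astype(object)
    return pd.DataFrame({"type": type_lab, "subtype": subtype,
                         "timepoint": tp, "sex": sex})


def _gene_table(config: SimConfig) -> pd.DataFrame:
    """Fixed gene layout: named genes first, then planted markers, then background."""
    n_mk = config.n_markers_per_type
    symbols: list[str] = list(OPSINS) + list(PANEL_GENES) + \
        list(PR_PROGRAM_GENES) + list(MITO_GENES)
    marker_of = [""] * len(symbols)
    # the photoreceptor program is itself a planted (shared) program
    for i, s in enumerate(symbols):
        if s in PR_PROGRAM_GENES:
            marker_of[i] = "photoreceptor"
    for ty, tag in ((R16, "R1-6"), (CONE, "cone"), (PIG1, "pigment1"),
                    (PIG23, "pigment23"), (NONEYE, "noneye")):
        for j in range(n_mk):
            symbols.append(f"mk-{tag}-{j + 1:02d}")
            marker_of.append(ty)
    for j in range(n_mk):   # shared inner-photoreceptor markers
        symbols.append(f"mk-R7.8-{j + 1:02d}")
        marker_of.append("R7/8")
    n_named = len(symbols)
    if config.n_genes < n_named:
        raise SimConfigError(
            f"n_genes={config.n_genes} too small for {n_named} structured genes")
    for j in range(config.n_genes - n_named):
        symbols.append(f"bg-{j + 1:04d}")
        marker_of.append("")
    return pd.DataFrame({
        "gene_id": [f"SIM{i:05d}" for i in range(config.n_genes)],
        "symbol": symbols,
        "marker_of": marker_of,
        "mito": [s.startswith("mt:") for s in symbols],
    })


def _mean_matrix(labels: pd.DataFrame, genes: pd.DataFrame,
                 config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Expected clean expression per (cell, gene), before size factors."""
    n, g = len(labels), len(genes)
    sym = {s: i for i, s in enumerate(genes["symbol"])}
    ty = labels["type"].to_numpy()
    sub = labels["subtype"].to_numpy()

    base = rng.lognormal(config.base_log_mean, config.base_log_sd, g)
    mu = np.tile(base, (n, 1))

    named = set(OPSINS) | set(PANEL_GENES)
    structured = ((genes["marker_of"] != "").to_numpy()
                  | genes["symbol"].isin(named).to_numpy()
                  | genes["mito"].to_numpy())
    mu[:, structured] = 0.0

    def col(s):
        return sym[s]

    is_r7 = ty == R7
    is_r8 = ty == R8
    is_pr = np.isin(ty, (R16, R7, R8))
    dra = sub == "DRA"

    mu[ty == R16, col("ninaE")] = config.ninae_mean
    mu[sub == "R7-pale", col("Rh3")] = config.opsin_mean
    mu[sub == "R7-yellow", col("Rh4")] = config.opsin_mean
    mu[sub == "R7-dorsal3", col("Rh3")] = config.opsin_mean / 2
    mu[sub == "R7-dorsal3", col("Rh4")] = config.opsin_mean / 2
    mu[sub == "R8-pale", col("Rh5")] = config.opsin_mean
    mu[sub == "R8-yellow", col("Rh6")] = config.opsin_mean
    mu[dra, col("Rh3")] = config.opsin_mean          # DRA R7/R8: Rh3 + hth only
    mu[dra, col("hth")] = 8.0
    mu[dra, col("Skeletor")] = 8.0

    mu[is_r8, col("sens")] = config.weak_panel_mean
    mu[is_r7, col("pros")] = config.weak_panel_mean
    mu[ty == CONE, col("ct")] = 30.0
    mu[ty == CONE, col("Crys")] = 50.0
    pig = np.isin(ty, (PIG1, PIG23))
    mu[pig, col("w")] = 15.0
    mu[pig, col("Pdh")] = 20.0
    mu[ty == PIG23, col("santa-maria")] = 10.0
    mu[ty == PIG1, col("wrapper")] = 10.0
    for s in NONEYE_MARKERS:
        mu[ty == NONEYE, col(s)] = 10.0

    pr_cols = [col(s) for s in PR_PROGRAM_GENES]
    pr_means = rng.lognormal(np.log(config.pr_program_mean), 0.5, len(pr_cols))
    mu[np.ix_(is_pr, pr_cols)] = pr_means

    marker_rows = genes.index[genes["marker_of"].isin(
        [R16, CONE, PIG1, PIG23, NONEYE, "R7/8"])].to_numpy()
    b = rng.lognormal(np.log(config.marker_base_mean),
                      config.marker_base_sd, len(marker_rows))
    mu[:, marker_rows] = b
    for k, gi in enumerate(marker_rows):
        target = genes["marker_of"][gi]
        home = np.isin(ty, (R7, R8)) if target == "R7/8" else (ty == target)
        mu[home, gi] = b[k] * config.marker_fold

    if config.sex_offset != 0.0:
        n_off = max(1, g // 20)
        off_cols = rng.choice(g, size=n_off, replace=False)
        fem = labels["sex"].to_numpy() == "F"
        mu[np.ix_(fem, off_cols)] *= np.exp(config.sex_offset)
    return mu


def synthesize_counts(labels: pd.DataFrame, config: SimConfig,
                      seed: int) -> CountMatrix:
    """Negative-binomial clean counts honouring the opsin-exclusivity table."""
    config.validate()
    known = set(config.proportions.keys())
    bad = sorted(set(labels["type"]) - known)
    if bad:
        raise SimConfigError(f"unknown cell-type label(s): {bad}")
    rng = _rng(seed)
    genes = _gene_table(config)
    mu = _mean_matrix(labels, genes, config, rng)
    theta = rng.gamma(config.disp_shape, config.disp_scale,
                      config.n_genes) + config.disp_floor
    ell = rng.lognormal(0.0, config.libsize_log_sd, len(labels))[:, None]
    lam = rng.gamma(theta[None, :], (mu * ell) / theta[None, :])
    counts = rng.poisson(lam).astype(np.int64)
    barcodes = np.array([f"CELL{i:06d}" for i in range(len(labels))],
                        dtype=object)
    return CountMatrix(sp.csr_matrix(counts), barcodes,
                       genes["gene_id"].to_numpy(dtype=object),
                       genes["symbol"].to_numpy(dtype=object))


def add_ambient_and_noise(clean: CountMatrix, labels: pd.DataFrame,
                          config: SimConfig, seed: int
                          ) -> tuple[CountMatrix, GroundTruth]:
    """Inject ambient soup, mitochondrial reads, doublets and depth decline.

    The soup profile is the clean dataset-wide expression profile (hence
    dominated by the most abundant transcript, ninaE).  A Binomial(N_c, rho_c)
    subset of each cell's molecules is *replaced* by multinomial soup draws,
    so library sizes are conserved and rho_c is interpretable as the
    contaminated fraction.  Mitochondrial counts are then added to reach a
    Beta-distributed target fraction, doublets are created by adding a random
    partner cell's profile, and library sizes are binomially thinned per
    timepoint by ``depth_decline``.
    """
    config.validate()
    rng = _rng(seed)
    genes = _gene_table(config)
    X = clean.densify().astype(np.int64)
    n, g = X.shape

    colsum = X.sum(axis=0).astype(float)
    total = colsum.sum()
    if total > 0:
        s = colsum / total
    else:
        s = np.full(g, 1.0 / g)

    rho = np.zeros(n)
    if config.rho_mean > 0:
        a = config.rho_mean * config.rho_conc
        b = (1 - config.rho_mean) * config.rho_conc
        rho = rng.beta(a, b, n)
        for c in range(n):
            N_c = int(X[c].sum())
            if N_c == 0:
                continue
            n_soup = rng.binomial(N_c, rho[c])
            if n_soup == 0:
                continue
            removed = rng.multivariate_hypergeometric(X[c], n_soup)
            X[c] = X[c] - removed + rng.multinomial(n_soup, s)

    mito_cols = genes.index[genes["mito"]].to_numpy()
    if config.mito_frac_mean > 0 and len(mito_cols):
        a = config.mito_frac_mean * config.mito_conc
        b = (1 - config.mito_frac_mean) * config.mito_conc
        f = rng.beta(a, b, n)
        N = X.sum(axis=1)
        m_add = np.round(f / (1 - f) * N).astype(np.int64)
        p_m = np.full(len(mito_cols), 1.0 / len(mito_cols))
        for c in np.where(m_add > 0)[0]:
            X[c, mito_cols] += rng.multinomial(m_add[c], p_m)

    doublet = np.zeros(n, dtype=bool)
    n_dbl = int(round(config.doublet_rate * n))
    if n_dbl > 0 and n > 1:
        hosts = rng.choice(n, size=n_dbl, replace=False)
        partners = rng.integers(0, n, size=n_dbl)
        partners = np.where(partners == hosts, (partners + 1) % n, partners)
        X[hosts] += X[partners]
        doublet[hosts] = True

    depth = dict(zip(config.timepoints, config.depth_decline))
    tp = labels["timepoint"].to_numpy()
    for t, d in depth.items():
        if d < 1.0:
            rows = np.where(tp == t)[0]
            X[rows] = rng.binomial(X[rows], d)

    observed = CountMatrix(sp.csr_matrix(X), clean.barcodes.copy(),
                           clean.gene_ids.copy(), clean.gene_symbols.copy())
    cells = labels.copy()
    cells["rho"] = rho
    cells["doublet"] = doublet
    cells.index = pd.Index(observed.barcodes, name="barcode")
    gt_genes = genes[["gene_id", "symbol", "marker_of", "mito"]].copy()
    gt_genes["soup_frac"] = s
    return observed, GroundTruth(cells=cells, genes=gt_genes)


def generate_retina_dataset(config: SimConfig
                            ) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Full generator: labels -> clean counts -> observed counts + truth.

    Returns (observed CountMatrix, per-cell annotation, GroundTruth).  Seeds
    for the three stages are derived from ``config.seed`` so a single integer
    reproduces the dataset bit for bit.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    labels = sample_cell_types(config, seeds[0])
    if config.n_cells == 0:
        genes = _gene_table(config)
        empty = CountMatrix(sp.csr_matrix((0, config.n_genes), dtype=np.int64),
                            np.array([], dtype=object),
                            genes["gene_id"].to_numpy(dtype=object),
                            genes["symbol"].to_numpy(dtype=object))
        gt_genes = genes[["gene_id", "symbol", "marker_of", "mito"]].copy()
        gt_genes["soup_frac"] = np.full(config.n_genes, 1.0 / config.n_genes)
        cells = labels.assign(rho=pd.Series(dtype=float),
                              doublet=pd.Series(dtype=bool))
        return empty, labels, GroundTruth(cells=cells, genes=gt_genes)
    clean = synthesize_counts(labels, config, seeds[1])
    observed, truth = add_ambient_and_noise(clean, labels, config, seeds[2])
    annotation = truth.cells[["type", "subtype", "timepoint", "sex"]].copy()
    return observed, annotation, truth


def write_dataset(directory: str | Path, matrix: CountMatrix,
                  annotation: pd.DataFrame, truth: GroundTruth,
                  config: SimConfig) -> None:
    """Write the 10x-style directory plus annotation, truth and config files."""
    directory = Path(directory)
    write_counts_mtx(matrix, directory)
    annotation.to_csv(directory / "annotation.tsv", sep="\t")
    truth.cells.to_csv(directory / "truth_cells.tsv", sep="\t")
    truth.genes.to_csv(directory / "truth_genes.tsv", sep="\t", index=False)
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(config).items()}
    cfg["proportions"] = dict(config.proportions)
    (directory / "sim_config.json").write_text(json.dumps(cfg, indent=1))
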