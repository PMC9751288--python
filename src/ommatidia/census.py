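"""Published cell-type census tables for adult fly-eye scRNA-seq datasets.

These tables record, per dataset, the number of cells assigned to each
major eye cell type together with the percentage as published, plus the
anatomically expected percentage per ommatidium (which
does not total 100 because bristle cells are not counted).  They serve as
worked examples for percentage/total arithmetic and as the reference
composition for the synthetic generator.

One printed value is internally inconsistent: the 1-day female R8 row
prints 7.4% for 386 of 5726 cells, which recomputes to 6.7%; every other
percentage cell recomputes to its printed precision.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

CELL_TYPES = ("R1-6", "R7", "R8", "cone", "pigment1", "pigment23")

#: anatomically expected percentage of each cell type per ommatidium
EXPECTED_PCT = {"R1-6": 30.0, "R7": 5.0, "R8": 5.0, "cone": 20.0,
                "pigment1": 10.0, "pigment23": 20.0}
EXPECTED_TOTAL_PCT = 90.0  # bristle cells are not counted

#: per-dataset cell counts with the percentage string as printed
SINGLE_DATASET_CENSUS: dict[str, dict[str, tuple[int, str]]] = {
    "1D_male": {"R1-6": (4079, "37"), "R7": (1770, "16"), "R8": (791, "7.1"),
                "cone": (28, "0.25"), "pigment1": (122, "1.1"),
                "pigment23": (4374, "39")},
    "3D_male": {"R1-6": (3538, "50"), "R7": (1251, "18"), "R8": (575, "8.2"),
                "cone": (56, "0.80"), "pigment1": (44, "0.63"),
                "pigment23": (1551, "22")},
    "7D_male": {"R1-6": (2460, "49"), "R7": (953, "19"), "R8": (504, "10"),
                "cone": (24, "0.48"), "pigment1": (48, "0.95"),
                "pigment23": (1046, "21")},
    "1D_female": {"R1-6": (3156, "55"), "R7": (965, "17"), "R8": (386, "7.4"),
                  "cone": (0, "0"), "pigment1": (0, "0"),
                  "pigment23": (1219, "21")},
}

#: the printed female R8 percentage that does not recompute from its counts
KNOWN_INCONSISTENT = {("1D_female", "R8")}

#: merged male+female 1-day dataset census (after joint reclustering)
MERGED_CENSUS: dict[str, dict[str, tuple[int, str]]] = {
    "1D_male": {"R1-6": (4150, "37"), "R7": (1739, "16"), "R8": (803, "7.2"),
                "cone": (32, "0.29"), "pigment1": (112, "1.0"),
                "pigment23": (4328, "38.8")},
    "1D_female": {"R1-6": (3064, "54"), "R7": (997, "17"), "R8": (449, "7.8"),
                  "cone": (6, "0.10"), "pigment1": (33, "0.58"),
                  "pigment23": (1177, "21")},
    "merged": {"R1-6": (7214, "43"), "R7": (2736, "16"), "R8": (1252, "7.4"),
               "cone": (38, "0.22"), "pigment1": (145, "0.86"),
               "pigment23": (5505, "33")},
}

#: library-quality metrics per dataset: median genes/cell, median UMI/cell
QUALITY_METRICS = {
    "1D_male": {"median_genes": 938, "median_umi": 3161},
    "3D_male": {"median_genes": 855, "median_umi": 3168},
    "7D_male": {"median_genes": 618, "median_umi": 1872},
    "1D_female": {"median_genes": 1008, "median_umi": 4465},
}

#: pale/yellow subtype counts: in-vivo antibody staining vs captured cells
PALE_YELLOW = {
    "R8_stain": (419, 1156),          # pale, yellow; ratio "about 30:70"
    "R7_stain": (244, 440),           # Rh3 vs Rh6 ommatidia, "about 30:70"
    "R8_capture_min": (58, 441),      # most pale-depleted captured dataset
    "R8_capture_max": (113, 678),
}


def census_table(which: str = "single") -> pd.DataFrame:
    """Tidy census with recomputed percentages alongside the printed ones."""
    source = SINGLE_DATASET_CENSUS if which == "single" else MERGED_CENSUS
    rows = []
    for ds, table in source.items():
        total = sum(c for c, _ in table.values())
        for ty, (count, printed) in table.items():
            rows.append((ds, ty, count, total, printed,
                         100.0 * count / total if total else np.nan))
    return pd.DataFrame(rows, columns=["dataset", "cell_type", "count",
                                       "total", "printed_pct",
                                       "recomputed_pct"])


def printed_precision_matches(recomputed: float, printed: str) -> bool:
    """True when ``recomputed`` rounds to the printed string's precision."""
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return abs(round(recomputed, decimals) - float(printed)) < 1e-9
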