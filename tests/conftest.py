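"""Shared fixtures: one default synthetic dataset and one pipeline run,
computed once per session and reused by every stage's tests."""
from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

import ommatidia as om
from ommatidia import cluster as cl
from ommatidia import pipeline as pl
from ommatidia.iocore import PipelineConfig

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_dataset():
    """5000-cell, 2000-gene synthetic retina with ground truth."""
    sim = om.SimConfig(n_cells=5000, seed=DEFAULT_SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, annotation, truth = om.generate_retina_dataset(sim)
    return {"sim": sim, "matrix": matrix, "annotation": annotation,
            "truth": truth}


@pytest.fixture(scope="session")
def default_run(default_dataset):
    """QC + ambient correction + clustering on the default dataset."""
    cfg = PipelineConfig(seed=DEFAULT_SEED, run_embedding=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qa = pl.qc_and_ambient(default_dataset["matrix"], cfg,
                               pl.stage_seed(DEFAULT_SEED, "qc"))
        result = cl.run_clustering(qa["corrected"], cfg,
                                   seed=pl.stage_seed(DEFAULT_SEED, "cluster"))
    truth_kept = default_dataset["truth"].cells.loc[qa["corrected"].barcodes]
    return {"cfg": cfg, "qa": qa, "corrected": qa["corrected"],
            "result": result, "truth_kept": truth_kept}


@pytest.fixture(scope="session")
def default_markers(default_run):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pl.marker_stage(default_run["result"],
                               default_run["corrected"],
                               default_run["cfg"])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
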