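import numpy as np
import pandas as pd
import pytest

import silkgland as sg
from silkgland.io import load_bundle, run_pipeline, write_synthetic_bundle

# Scaled-down gene architecture used where full-size simulation is overkill.
SMALL_CONFIG = {
    "n_genes": 600,
    "genes": {"n_markers_per_type": 10, "n_head_markers": 30,
              "n_other_markers": 30, "n_silent": 60},
    "cells": {"n_cells": 600, "n_samples": 2, "scale": 1.0},
    "spatial": {"n_sections": 2, "spots_per_region": 6},
    "histology": {"n_vesicles": {"A": 30, "B": 12, "C": 12},
                  "n_lumen_per_layer": 10},
}


@pytest.fixture(scope="session")
def small_design():
    return sg.make_design(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_design():
    return sg.make_design()


@pytest.fixture(scope="session")
def default_sim(default_design):
    """One full-size transcriptome simulation shared across tests."""
    bulk, cells, spatial, spots, truth = sg.simulate_transcriptomes(default_design, 11)
    return dict(bulk=bulk, cells=cells, spatial=spatial, spots=spots, truth=truth)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory, default_design):
    outdir = tmp_path_factory.mktemp("bundle")
    manifest = write_synthetic_bundle(default_design, 11, outdir)
    return load_bundle(manifest)


@pytest.fixture(scope="session")
def pipeline_results(tmp_path_factory, default_bundle):
    outdir = tmp_path_factory.mktemp("results")
    return run_pipeline(default_bundle, outdir, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_bulk_matrix(values: np.ndarray, tissues: list[str],
                     lengths: np.ndarray | None = None):
    """Small helper to assemble an ExpressionMatrix from an array."""
    n_genes, n_units = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    units = [f"{t}_r{i}" for i, t in enumerate(tissues)]
    meta = pd.DataFrame({"tissue": tissues, "replicate": range(n_units)}, index=units)
    gl = pd.Series(lengths if lengths is not None else np.full(n_genes, 1000.0),
                   index=genes)
    return sg.ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=units),
        layer="counts", unit_meta=meta, gene_lengths=gl,
    )
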