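"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from csgcnreg import csgcn_core as cc
from csgcnreg import gem_io
from csgcnreg import synthetic_data as sd

PLANTED_SEED = 1
SAMPLES_PER_CONDITION = {"normal": 100, "tumor_a": 100, "tumor_b": 100}


@pytest.fixture(scope="session")
def planted_bundle():
    """Benchmark dataset: 200 genes, 3 conditions x 100 samples, 20
    planted condition-specific edges at target Spearman 0.85."""
    return sd.generate_dataset(
        200, SAMPLES_PER_CONDITION, sd.TruthSpec(), seed=PLANTED_SEED
    )


@pytest.fixture(scope="session")
def planted_normalized(planted_bundle):
    gem, annot, truth = planted_bundle
    return gem_io.log2_quantile_normalize(gem), annot, truth


@pytest.fixture(scope="session")
def planted_edges_built(planted_normalized):
    """csGCN built over the planted-pair gene subset (the quadratic
    all-pairs stage is restricted to keep the suite fast)."""
    norm, annot, truth = planted_normalized
    genes = sorted({g for e in truth.planted_edges for g in (e.gene_a, e.gene_b)})
    edges = cc.build_csgcn(
        norm, annot, cc.CsgcnParams(seed=PLANTED_SEED, genes=genes)
    )
    return edges, truth


@pytest.fixture
def tiny_gem():
    """3 genes x 4 samples, linear scale, one missing cell."""
    values = pd.DataFrame(
        [[1.0, 2.0, 4.0, 8.0], [2.0, 4.0, np.nan, 16.0], [3.0, 6.0, 12.0, 24.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return gem_io.GEM(values, scale=gem_io.LINEAR)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
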