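"""Shared fixtures: synthetic datasets and preprocessed gene-level matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tcellgrn import io_preprocess as iop
from tcellgrn import synthetic as syn


def preprocess_to_genes(matrix: iop.ExpressionMatrix, annotation: pd.DataFrame) -> iop.ExpressionMatrix:
    """The standard chain: quantile-normalize, filter, collapse, batch-center."""
    m = iop.quantile_normalize(matrix)
    tau = iop.estimate_background(m)
    m = iop.filter_expressed(m, tau)
    m = iop.collapse_probes(m)
    return iop.center_batches(m, annotation)


def simulate_default(seed: int, **overrides):
    config = syn.SyntheticConfig(seed=seed, **overrides)
    truth = syn.generate_ground_truth(config)
    matrix, annotation = syn.simulate_expression(truth, config)
    return config, truth, matrix, annotation


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset, probe level."""
    return simulate_default(seed=11)


@pytest.fixture(scope="session")
def gene_level_dataset(default_dataset):
    """The default dataset pushed through the preprocessing chain."""
    config, truth, matrix, annotation = default_dataset
    return config, truth, preprocess_to_genes(matrix, annotation), annotation


def toy_matrix(values, genes=None, samples=None, gene_map=None) -> iop.ExpressionMatrix:
    values = np.asarray(values, float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    gm = pd.Series(gene_map, index=genes) if gene_map is not None else None
    return iop.ExpressionMatrix(values=pd.DataFrame(values, index=genes, columns=samples),
                                gene_map=gm)
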