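import numpy as np
import pandas as pd
import pytest

import pluriscreen as ps


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic compendium (seed 0) shared across tests."""
    cfg = ps.SimulationConfig(seed=0)
    matrix, metadata, annotation, truth = ps.generate_dataset(cfg)
    return matrix, metadata, annotation, truth


@pytest.fixture(scope="session")
def default_screen(default_dataset):
    """Full pipeline result on the default dataset."""
    matrix, metadata, annotation, truth = default_dataset
    res = ps.run_full_screen(matrix, metadata, annotation, ps.pgm_gene_set(truth))
    return res, truth


def make_log_matrix(values: np.ndarray, genes=None, samples=None) -> ps.ExpressionMatrix:
    """Wrap an array as a log2(FPKM+1)-state matrix for unit tests."""
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    return ps.ExpressionMatrix(df, "log2p1")


def make_raw_matrix(values: np.ndarray, genes=None, samples=None) -> ps.ExpressionMatrix:
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    return ps.ExpressionMatrix(df, "raw_fpkm")
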